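# Methods

This note records the models implemented in `dendritic`, the parameter
choices that matter, what the synthetic data do and do not emulate, and the
numerical decisions a user should know before trusting a number.

## Brownian-ratchet rate laws (`dendritic.ratchet`)

A filament end growing against a surface accepts a new subunit only when a
thermal fluctuation opens a gap of size δ; the insertion rate constant is
reduced by `B = exp(−f·δ·sinθ/kBT)`.

* **kBT = 4.114 pN·nm** (298 K), configurable. Room temperature is assumed
  because nothing in the model depends sharply on T.
* **Gap sizes.** δ_actin = δ_cap(wt) = 2.7 nm — monomeric actin and wildtype
  capping protein require the same gap, equal to the filament rise per
  subunit. The bulky CP variant's gap is not known structurally; the default
  δ_bulky = 5.4 nm (2×) is a configurable placeholder, and the tether fit
  treats it as fixed input, not a fitted quantity.
* **Contact angle.** A single effective angle per state,
  sinθ = E/(C_A·602.2·rise), rather than an orientation distribution: E ends
  per area piercing a network of filament length density L_v =
  C_A·602.2·rise (µm per µm³) imply exactly this sine. Ratios in
  (1, 1+10⁻³] are clamped to 1 (float slack at the perpendicular bound);
  anything larger raises a geometric-inconsistency error rather than being
  silently clamped, to surface bad inputs.
* **Load sharing.** External stress × area divided equally over free barbed
  ends; no force distribution across filaments.
* **Tethering force.** Transient NPF–barbed-end links act as friction
  opposing motion; modelled as a constant additive per-filament force
  applied identically at all loads (including zero) in both the elongation
  and capping factors. An explicit attachment/detachment kinetics for the
  tether was deliberately not introduced — it would add parameters the
  ratio data cannot constrain. The fit minimizes χ² over f_tether ≥ 0 with
  everything else fixed; the confidence interval is a parametric bootstrap
  (Gaussian per-point errors around the fitted model, 500 refits,
  2.5/97.5 percentiles).

## Flux-balance analysis (`dendritic.flux`)

* **Steady segments.** Blocks of near-constant stress are found from a
  rolling-median stress trace (boundaries where the jump exceeds
  max(1 Pa, 2% of level, 6× the MAD noise scale)); within a block the start
  is advanced past the adaptation transient until the height-vs-time OLS
  fit reaches r² ≥ 0.99, and blocks shorter than 60 s are dropped. The
  thresholds are defaults, not measurements; they were chosen so that an
  exactly linear phase is recovered to machine precision and a 10 nm-noise
  trace at 1 Hz recovers its slope within 2%.
* **Rates.** Per-network rate = component density × velocity, normalized to
  the 25 Pa reference load (configurable); per-filament rate divides by the
  relative free-end density. Both are exactly 1 at the reference by
  construction.
* **Decay fits** use multi-start nonlinear least squares (≥6 log-spaced
  initial decay constants); two-component fits order the constants
  ascending to resolve the label-swap degeneracy. Constant data raise a
  degenerate-fit error instead of returning an unbounded constant.
* **Mesh size** implements the literal formula ζ = 1.47/√C_A (µm, C_A in
  µM). Note a documented discrepancy: at ~1250 µM the formula gives
  41.6 nm while the commonly quoted figure for such networks is 45 nm; the
  diffusion-impact threshold operation (0.4·ζ) therefore takes the mesh
  size as an explicit input rather than recomputing it.
* **Baseline subtraction** removes a constant per-channel pre-nucleation
  (lag-phase) signal over a user-specified window.

## Stochastic network simulator (`dendritic.simulate`)

Exact SSA over {nucleate, elongate-by-one, cap} with propensities refreshed
after every event. Nucleation feedback is WH2-occupancy saturation
φ = E·K_be/(1+E·K_be) (barbed-end interference); the functional form is a
modelling choice — the phenomenon (occupancy rising ~7%→27% with a ~20%
nucleation drop) is established, its law is not. K_be = 5×10⁻⁴ µm² makes
φ ≈ 0.07 at the unloaded steady state of the default parameters. Mother
filaments are assumed non-limiting; pointed ends are inert (profilin);
elongation is coarse-grained to single-subunit steps at k_on0
(≡ k_on·[profilin-actin], default 83 s⁻¹ giving ≈7.3 µm/min unloaded);
capping at k_cap0 (≡ k_cap·[CP], default 0.48 s⁻¹ giving E* ≈ 150 µm⁻²,
the default used for sinθ elsewhere). An optional early-failure hazard for
young branches exists but is off by default, and deliberately carries no
force dependence.

Because the local polymer length density near the surface is geometrically
slaved to E and sinθ (n = E/(rise·sinθ)), the angle cannot be inferred from
the simulation state alone; `SimParams.polymer_conc` (default 150 µM, an
unloaded-network observable) anchors it, and sinθ = min(1, E/L_v) is
recomputed every event. Height advances by rise·sinθ/n per elongation
event. If nonzero stress meets zero uncapped filaments the force coupling
pauses (boundary carries the load) and the episode is logged.

The independent oracle is the mean-field fixed point
k_nuc_max·npf·(1−φ(E)) = k_cap0·B(σ/E+f_tether, δ_cap, sinθ(E))·E, solved
by bracketing/brentq; tests require agreement within 3 SE (batch-means SE
for E, Poisson SEs for fluxes) over a 12-point parameter grid. Desk-scale
test runs use area 1 µm², k_on0 = 20 s⁻¹ and 150 s durations — chosen so a
run holds ~150 filaments (finite-size bias in E is ≲1% there, and grows to
~2% at 0.25 µm²) while a few hundred thousand events complete in well
under a second.

## Single-molecule analysis (`dendritic.single_molecule`)

Productive tracks decay as I₀·exp(−v·t/d); the evanescent depth default
d = 0.15 µm is a typical TIRF value and a *generator* parameter, not a
measurement. Classification replaces an image-based expert/random-forest
workflow with deterministic feature rules on track tables: single-
exponential fit r² ≥ 0.9 → productive; ≥80% intensity drop and no
truncation → continuous, otherwise abortive; flat/blinking intensity with
<0.2 µm drift → unproductive; <5 frames → unclassified. Dwell = time to
5% of fitted I₀ (or track end); truncation flag at a final intensity above
20% of I₀. The generator counts a detachment as abortive only while the
molecule is still clearly in the field (model intensity above 25% of I₀);
later detachments are observationally complete transits, which keeps
noise-free generator labels and classifier output in exact agreement. The
abortive hazard is exposed with no claimed force dependence. The per-NPF
nucleation rate divides the productive-event area rate by the labeled
fraction and the NPF density (1850 µm⁻² default). Dwell excess is
Σ max(0, p_loaded − p_control) over shared histogram bins with a
resampling CI; the positive part localizes to short dwells by construction.

## FRET occupancy (`dendritic.fret`)

Two-population model: unprotected donors quench fast (k1), protected donors
decay only by bleaching (k2 ≪ k1, fixed from controls):
I(t) = (1−p)e^(−k1·t) + p·e^(−k2·t). Bleaching of the fast population
during the fast phase is neglected (k1 ≫ k2 asserted; fits with k1 ≤ k2
raise a phase-separation error). p is computed from the fast-phase
*amplitudes* relative to a no-network reference rather than from plateaus,
which is robust to finite acquisition windows; estimates outside [0,1] are
clipped with a warning. The defaults used in tests and drivers (k1 = 1 s⁻¹,
k2 = 0.02 s⁻¹, 12 s curves at 20 Hz) give k1/k2 = 50 and cover 12 fast-phase
time constants. The unloaded ground truth is taken as 7.3% — the unrounded
value consistent with a 27% loaded fraction and a ~3.7-fold change (27/7
of the rounded prints would be 3.86).

## Synthetic data (`dendritic.synth`)

The generators emulate: stepwise force clamps with exponential adaptation
transients (τ = 15 s) into linear growth, 10 nm Gaussian height noise at
1 Hz, 1 Pa clamp noise; per-channel density plateaus with 2% noise sharing
one response (so stoichiometry is load-invariant); a monotone barbed-end
series reaching 3.3× at 1020 Pa; per-network fluxes declining linearly to
50% at 1200 Pa with velocity defined as flux/density (7.3 µm/min unloaded);
and wt/bulky ratios from the ratchet model with 5% log-normal noise
averaged over 100 replicate networks per load (a single replicate leaves
the 0.3 pN tether unidentifiable at the ±20% level: the log-ratio
sensitivity is ∂y/∂f_t = (δ_b−δ_wt)/kBT·(sinθ−sinθ_ref) ≤ 0.2 pN⁻¹, so
SE(f̂) ≈ 0.14 pN at one replicate and ≈0.014 pN at 100). Response curves
are smooth parametric stand-ins shaped to the measured phenomenology, not
curves fitted to any particular dataset. All generators are byte-deterministic under a fixed
seed (one RNG stream per call, seed recorded in CSV header comments).

What they do **not** emulate: image-level structure (PSFs, background
gradients, pixel noise), drift and stage artifacts, photobleaching of bulk
channels, network elasticity/buckling, spatial heterogeneity across the
pattern, or correlated clamp noise. Passing tests therefore demonstrate
estimator correctness under the stated statistical model, not robustness
to every instrumental pathology.

## Known limitations

* The simulator has no spatial filament geometry, excluded volume,
  severing or elastic mechanics; only steady states are meaningful, and the
  adaptation transients it produces are not calibrated.
* The single effective contact angle suppresses orientation-distribution
  effects; under strong load anisotropy the ratchet factors would differ.
* δ_bulky is a placeholder; quantitative wt/bulky predictions inherit its
  uncertainty, though the tether fit conditions on it explicitly.
* CSV float round-trips are exact only to the 9-significant-digit format
  used by the writers.
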