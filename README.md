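# dendritic — load adaptation in branched actin networks

Branched (dendritic) actin networks are the self-assembling motors that push
cell membranes forward: surface-bound nucleation promoting factors (NPFs,
here WAVE1ΔN) activate the Arp2/3 complex to nucleate filaments, profilin–
actin elongates their free barbed ends, and capping protein (CP) terminates
them. Under compressive load these networks grow slower but *denser*, while
their composition and mean filament length barely change. This package
implements the quantitative machinery needed to dissect that adaptation from
AFM force-clamp + TIRF measurements — and to rehearse every analysis on
synthetic data with known ground truth. It is aimed at cytoskeletal
biophysicists who want the flux algebra, the ratchet model and the
estimators as tested, reusable code.

## The model in brief

At steady state the network-level nucleation and capping rates balance:

    R_cap = k_cap [CP] E = R_nucleate   ⇒   E = R_nucleate / (k_cap [CP])

with `E` the surface density of free barbed ends (µm⁻²). Force enters
through a Brownian-ratchet law: inserting a subunit of gap size δ against a
per-filament load f (stress shared equally over free ends, plus a small
internal tethering force) succeeds with probability

    B = exp(−f · δ · sinθ / kBT),    sinθ = E / (C_A · 602.2 · rise)

where θ is the filament contact angle estimated from the barbed-end and
polymeric-actin densities. Monomeric actin and wildtype CP both need
δ = 2.7 nm, so elongation and capping slow identically under load and
filament length stays constant; an engineered "bulky" CP needs a larger gap
and falls behind — the direct test of the ratchet mechanism, and the handle
by which the single free parameter (the tethering force) is fitted.

Around this core the package provides:

* `dendritic.flux` — steady-segment detection in force-clamp traces, growth
  velocities, per-network/per-filament rates, exponential force-response fits.
* `dendritic.simulate` — an exact (Gillespie) stochastic simulator of
  nucleation/elongation/capping with load sharing and barbed-end
  interference, with a mean-field fixed point as its independent oracle.
* `dendritic.single_molecule` — transit/dwell analysis of single Arp2/3
  tracks and the per-NPF nucleation rate.
* `dendritic.fret` — WH2 occupancy from donor-quench kinetics with a fixed
  bleaching rate.
* `dendritic.synth` — seeded generators for every input table.

## Worked example

The numbered drivers under `analysis/` run the whole chain on synthetic
data (`python analysis/01_generate_datasets.py`, then 02…06). The flux
stage, for instance, prints:

```
steady segments:
 t_start  t_end  stress_pa  velocity_um_min  r_squared
     0.0  359.0      0.039            7.300        1.0
   360.0  719.0     25.030            6.535        1.0
   720.0 1079.0    255.010            3.923        1.0
  1080.0 1439.0    509.944            2.959        1.0
  1440.0 1799.0   1019.878            1.926        1.0
  1800.0 2159.0   1199.964            1.633        1.0

per-filament actin rate vs force/filament: single-exponential decay constant 1.19 pN (r²=0.9839)
per-filament actin rate vs stress: double-exponential constants [ 69.7 986.7] Pa (r²=0.9998)
per-network actin rate at the stall-proximal hold: 50.8% of reference
```

The unloaded network grows at 7.3 µm/min; per-network incorporation rates
fall to ~50% of the 25 Pa reference near the ~1200 Pa stall; and the
per-filament rates that look double-exponential in stress collapse to a
single exponential in force per filament — the ratchet signature. The
single-molecule stage recovers the 0.037 s⁻¹ per-NPF nucleation rate from a
Poisson event stream over 1850 NPFs/µm², the FRET stage recovers the 7% →
27% (~3.7-fold) rise in barbed-end-protected WH2 domains, and the tether
fit returns ≈0.3 pN from the wildtype/bulky ratio data.

A CLI mirrors the stages for file-based use
(`dendritic gen-data | simulate | analyze-flux | analyze-sm | analyze-fret |
fit-tether`); every run writes a `run_log.txt` provenance block.

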