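"""Event-driven stochastic simulation of branched-network growth under load.

The network is reduced to its surface kinetics: nucleation creates new
filaments at surface-immobilized NPFs, free barbed ends elongate one subunit
at a time, and capping protein terminates them.  Three couplings make the
model nontrivial:

* **Load sharing** — the clamped stress times the pattern area is divided
  equally over the current uncapped filaments; that per-filament force (plus
  the internal tethering force) enters the Brownian-ratchet factors that
  slow both elongation and capping.
* **Barbed-end interference** — free barbed ends occupy NPF WH2 domains,
  with occupancy φ = E·K_be / (1 + E·K_be), and only unoccupied NPFs
  nucleate: R_nuc = k_nuc_max · npf_density · area · (1 − φ).  This is the
  negative feedback that keeps the filament density homeostatic.
* **Geometry** — the effective filament contact angle satisfies
  sinθ = E / (C_A·602.2·rise), recomputed from the current barbed-end
  density against a fixed surface polymer concentration, and each added
  subunit advances the surface by rise·sinθ.

Events are drawn with the exact Gillespie algorithm (propensities refreshed
after every event); trajectories are sampled on a fixed grid and summarized
by stationary time averages whose defining property is flux balance,
R_cap ≈ R_nucleate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import DomainError, InsufficientDataError, StationarityWarning
from .ratchet import RatchetParams

__all__ = [
    "SimParams",
    "SimTrajectory",
    "SteadyStateSummary",
    "simulate",
    "steady_state_summary",
    "load_series_experiment",
    "mean_field_barbed_end_density",
]


@dataclass(frozen=True)
class SimParams:
    """Kinetic and geometric parameters of the network-growth simulation.

    k_nuc_max : s⁻¹ — nucleation rate per NPF at zero WH2 occupancy
        (default 0.037, the measured unloaded per-NPF rate).
    npf_density : µm⁻² — surface density of NPF molecules (default 1850).
    area : µm² — pattern area carrying the load.
    k_on0 : s⁻¹ — unloaded elongation rate per filament (subunits/s;
        k_on·[profilin-actin] coarse-grained into one constant).  The
        default 83 yields ≈7.3 µm/min unloaded growth at the default
        geometry.
    k_cap0 : s⁻¹ — unloaded capping rate per filament (k_cap·[CP]).
    K_be : µm² — barbed-end/NPF association scale of the occupancy law
        φ = E·K_be/(1+E·K_be); default gives φ ≈ 0.07 at the unloaded
        steady state.
    polymer_conc : µM — surface polymeric-actin concentration used for the
        contact-angle estimate (an observable of real networks; here a
        fixed parameter, see docs/methods.md).
    abortive_hazard : s⁻¹ — optional early-failure rate for young branches
        (0 disables); abortive_window : s — age window in which it acts.
    stress_schedule : [(time s, stress Pa), ...] — force-clamp setpoints.
    """

    k_nuc_max: float = 0.037
    npf_density: float = 1850.0
    area: float = 1.0
    k_on0: float = 83.0
    k_cap0: float = 0.48
    K_be: float = 5.0e-4
    polymer_conc: float = 150.0
    abortive_hazard: float = 0.0
    abortive_window: float = 0.0
    ratchet: RatchetParams = field(default_factory=RatchetParams)
    stress_schedule: tuple = ((0.0, 0.0),)
    seed: int = 0

    def __post_init__(self):
        for name in ("k_nuc_max", "npf_density", "k_on0", "k_cap0", "K_be",
                     "abortive_hazard", "abortive_window"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.area <= 0 or self.polymer_conc <= 0:
            raise DomainError("area and polymer_conc must be > 0")
        times = [t for t, _ in self.stress_schedule]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DomainError("stress_schedule times must be increasing")
        if any(s < 0 for _, s in self.stress_schedule):
            raise DomainError("stresses must be >= 0")


@dataclass
class SimTrajectory:
    """Sampled state of one simulation run.

    Arrays are aligned on ``time``; event counters are cumulative.
    ``capped_lengths``/``capped_times`` record the final subunit count and
    time of every capping event; ``paused_episodes`` counts intervals where
    nonzero stress met zero uncapped filaments (load carried by the
    boundary, force coupling suspended).
    """

    time: np.ndarray
    free_ends: np.ndarray
    polymer_subunits: np.ndarray
    height: np.ndarray
    wh2_occupancy: np.ndarray
    nucleation_events: np.ndarray
    capping_events: np.ndarray
    elongation_events: np.ndarray
    stress: np.ndarray
    capped_lengths: np.ndarray
    capped_times: np.ndarray
    params: SimParams
    paused_episodes: int = 0


class _Rng:
    """Chunked draws from a numpy Generator (per-event overhead matters)."""

    def __init__(self, seed, chunk=16384):
        self.gen = np.random.default_rng(seed)
        self.chunk = chunk
        self._exp = self.gen.standard_exponential(chunk)
        self._uni = self.gen.random(chunk)
        self._ie = 0
        self._iu = 0

    def exponential(self):
        if self._ie >= self.chunk:
            self._exp = self.gen.standard_exponential(self.chunk)
            self._ie = 0
        v = self._exp[self._ie]
        self._ie += 1
        return v

    def uniform(self):
        if self._iu >= self.chunk:
            self._uni = self.gen.random(self.chunk)
            self._iu = 0
        v = self._uni[self._iu]
        self._iu += 1
        return v


def _stress_at(schedule, t):
    s = schedule[0][1]
    for t0, sigma in schedule:
        if t >= t0:
            s = sigma
        else:
            break
    return s


def simulate(
    params: SimParams,
    duration: float,
    sample_dt: float = 0.5,
    initial_filaments: int = 0,
) -> SimTrajectory:
    """Exact stochastic simulation of network growth for ``duration`` s.

    Events are {nucleate, elongate-by-one, cap}; propensities are
    recomputed after every event, sinθ included.  Fully reproducible for a
    fixed ``params.seed``.  ``initial_filaments`` seeds the run with that
    many one-subunit filaments (useful with nucleation switched off).
    """
    if duration <= 0:
        raise DomainError("duration must be > 0")
    p = params
    consts = p.ratchet.constants
    rise = consts.subunit_rise_um
    lv = p.polymer_conc * consts.molarity_to_density * rise  # µm⁻² length density
    kBT = consts.kBT
    d_act = p.ratchet.delta_actin
    d_cap = p.ratchet.delta_cap_wt
    f_teth = p.ratchet.f_tether

    rng = _Rng(p.seed)
    lengths = np.ones(max(1024, 2 * initial_filaments), dtype=np.int64)
    n = initial_filaments  # uncapped filament count; lengths[:n] valid
    subunits = initial_filaments
    height = 0.0
    t = 0.0
    n_nuc = n_cap = n_el = 0
    capped_lengths: list[int] = []
    capped_times: list[float] = []
    paused = 0
    in_pause = False

    n_samples = int(math.floor(duration / sample_dt)) + 1
    s_time = np.arange(n_samples) * sample_dt
    s_free = np.zeros(n_samples)
    s_poly = np.zeros(n_samples)
    s_h = np.zeros(n_samples)
    s_phi = np.zeros(n_samples)
    s_nuc = np.zeros(n_samples)
    s_capev = np.zeros(n_samples)
    s_el = np.zeros(n_samples)
    s_sig = np.zeros(n_samples)
    isamp = 0

    nuc_area = p.k_nuc_max * p.npf_density * p.area

    while True:
        E = n / p.area
        phi = (E * p.K_be) / (1.0 + E * p.K_be)
        sigma = _stress_at(p.stress_schedule, t)
        if n > 0:
            sin_theta = min(1.0, E / lv)
            f_eff = sigma * p.area / n + f_teth
            work = f_eff * sin_theta / kBT
            b_el = math.exp(-work * d_act)
            b_cap = math.exp(-work * d_cap)
            a_el = n * p.k_on0 * b_el
            a_cap = n * p.k_cap0 * b_cap
            in_pause = False
        else:
            # no uncapped filaments: force per filament undefined; the
            # boundary carries the stress until the next nucleation
            sin_theta = 0.0
            a_el = a_cap = 0.0
            if sigma > 0 and not in_pause:
                paused += 1
                in_pause = True
        a_nuc = nuc_area * (1.0 - phi)
        a_tot = a_nuc + a_el + a_cap
        if a_tot <= 0.0:
            t = duration
        else:
            t += rng.exponential() / a_tot

        while isamp < n_samples and s_time[isamp] <= t:
            s_free[isamp] = n
            s_poly[isamp] = subunits
            s_h[isamp] = height
            s_phi[isamp] = phi
            s_nuc[isamp] = n_nuc
            s_capev[isamp] = n_cap
            s_el[isamp] = n_el
            s_sig[isamp] = _stress_at(p.stress_schedule, s_time[isamp])
            isamp += 1
        if t >= duration:
            break

        u = rng.uniform() * a_tot
        if u < a_nuc:
            if n >= lengths.size:
                lengths = np.concatenate([lengths, np.ones_like(lengths)])
            lengths[n] = 1
            n += 1
            subunits += 1
            n_nuc += 1
        elif u < a_nuc + a_el:
            idx = int(rng.uniform() * n)
            lengths[idx] += 1
            subunits += 1
            n_el += 1
            height += rise * sin_theta / n
        else:
            idx = int(rng.uniform() * n)
            capped_lengths.append(int(lengths[idx]))
            capped_times.append(t)
            lengths[idx] = lengths[n - 1]
            n -= 1
            n_cap += 1

    return SimTrajectory(
        time=s_time, free_ends=s_free, polymer_subunits=s_poly, height=s_h,
        wh2_occupancy=s_phi, nucleation_events=s_nuc, capping_events=s_capev,
        elongation_events=s_el, stress=s_sig,
        capped_lengths=np.asarray(capped_lengths, dtype=float),
        capped_times=np.asarray(capped_times, dtype=float),
        params=p, paused_episodes=paused,
    )


@dataclass(frozen=True)
class SteadyStateSummary:
    """Window time-averages with standard errors and the balance residual."""

    stress: float
    mean_free_end_density: float  # µm⁻²
    se_free_end_density: float
    velocity: float  # µm/min
    polymer_flux: float  # subunits·s⁻¹·µm⁻²
    nucleation_flux: float  # s⁻¹·µm⁻²
    se_nucleation_flux: float
    capping_flux: float  # s⁻¹·µm⁻²
    se_capping_flux: float
    balance_residual: float  # |R_cap − R_nuc| / R_nuc
    mean_capped_length: float  # subunits
    se_capped_length: float
    wh2_occupancy: float
    stationary: bool


def _batch_se(x: np.ndarray, n_batches: int = 8) -> float:
    """Batch-means standard error (robust to autocorrelation)."""
    n = x.size
    if n < 2 * n_batches:
        return float(np.std(x, ddof=1) / math.sqrt(max(n, 2))) if n > 1 else float("nan")
    usable = n - n % n_batches
    means = x[:usable].reshape(n_batches, -1).mean(axis=1)
    return float(np.std(means, ddof=1) / math.sqrt(n_batches))


def steady_state_summary(
    traj: SimTrajectory, window: tuple[float, float]
) -> SteadyStateSummary:
    """Time-averaged observables over a stationary window of the trajectory.

    Fluxes come from event-count differences over the window; the
    flux-balance residual |R_cap − R_nuc|/R_nuc is the key stationarity
    diagnostic.  A significant linear trend in the free-end count (5%
    level) marks the summary non-stationary and raises a
    :class:`StationarityWarning`.
    """
    t0, t1 = window
    mask = (traj.time >= t0) & (traj.time <= t1)
    if mask.sum() < 4:
        raise InsufficientDataError("window contains too few samples")
    i0 = int(np.flatnonzero(mask)[0])
    i1 = int(np.flatnonzero(mask)[-1])
    dt = traj.time[i1] - traj.time[i0]
    area = traj.params.area
    d_nuc = traj.nucleation_events[i1] - traj.nucleation_events[i0]
    d_cap = traj.capping_events[i1] - traj.capping_events[i0]
    d_el = traj.elongation_events[i1] - traj.elongation_events[i0]
    if d_nuc + d_cap + d_el == 0:
        raise InsufficientDataError("no events in the window")

    e_density = traj.free_ends[mask] / area
    lr = stats.linregress(traj.time[mask], e_density)
    stationary = bool(lr.pvalue > 0.05)
    if not stationary:
        warnings.warn(
            f"free-end density trends over the window (p={lr.pvalue:.3g})",
            StationarityWarning,
        )

    r_nuc = d_nuc / (dt * area)
    r_cap = d_cap / (dt * area)
    se_nuc = math.sqrt(max(d_nuc, 1.0)) / (dt * area)
    se_cap = math.sqrt(max(d_cap, 1.0)) / (dt * area)
    vel = np.polyfit(traj.time[mask], traj.height[mask], 1)[0] * 60.0

    lmask = (traj.capped_times >= t0) & (traj.capped_times <= t1)
    clens = traj.capped_lengths[lmask]
    mean_len = float(clens.mean()) if clens.size else float("nan")
    se_len = (
        float(clens.std(ddof=1) / math.sqrt(clens.size)) if clens.size > 1 else float("nan")
    )
    return SteadyStateSummary(
        stress=float(np.median(traj.stress[mask])),
        mean_free_end_density=float(e_density.mean()),
        se_free_end_density=_batch_se(e_density),
        velocity=float(vel),
        polymer_flux=d_el / (dt * area),
        nucleation_flux=r_nuc,
        se_nucleation_flux=se_nuc,
        capping_flux=r_cap,
        se_capping_flux=se_cap,
        balance_residual=abs(r_cap - r_nuc) / r_nuc if r_nuc > 0 else float("nan"),
        mean_capped_length=mean_len,
        se_capped_length=se_len,
        wh2_occupancy=float(traj.wh2_occupancy[mask].mean()),
        stationary=stationary,
    )


def load_series_experiment(
    params: SimParams,
    stresses: Sequence[float],
    hold: float = 60.0,
    burn_in: float = 20.0,
    sample_dt: float = 0.5,
) -> list[SteadyStateSummary]:
    """In-silico stress ladder: hold each stress, summarize the steady tail.

    The stresses are applied in the given (ascending) order in a single
    continuous run, mimicking a force-clamp staircase; each hold's final
    ``hold − burn_in`` seconds are summarized.
    """
    if any(b < a for a, b in zip(stresses, stresses[1:])):
        raise DomainError("stresses must be ordered ascending")
    if burn_in >= hold:
        raise DomainError("burn_in must be shorter than hold")
    schedule = tuple((i * hold, s) for i, s in enumerate(stresses))
    p = replace(params, stress_schedule=schedule)
    traj = simulate(p, duration=hold * len(stresses), sample_dt=sample_dt)
    out = []
    for i, _ in enumerate(stresses):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", StationarityWarning)
            out.append(
                steady_state_summary(
                    traj, (i * hold + burn_in, (i + 1) * hold - 1e-9)
                )
            )
    return out


def mean_field_barbed_end_density(params: SimParams, stress: float = 0.0) -> float:
    """Deterministic fixed point E* of the mean-field rate balance.

    Solves k_nuc_max·npf·(1−φ(E)) = k_cap0·B(σ/E + f_tether, δ_cap, sinθ(E))·E
    by bracketing and root finding; the independent oracle for the
    simulator's stationary free-end density.
    """
    p = params
    consts = p.ratchet.constants
    lv = p.polymer_conc * consts.molarity_to_density * consts.subunit_rise_um

    def balance(e):
        phi = e * p.K_be / (1.0 + e * p.K_be)
        sin_theta = min(1.0, e / lv)
        f_eff = stress / e + p.ratchet.f_tether
        b_cap = math.exp(-f_eff * p.ratchet.delta_cap_wt * sin_theta / consts.kBT)
        return p.k_nuc_max * p.npf_density * (1.0 - phi) - p.k_cap0 * b_cap * e

    lo, hi = 1e-9, 10.0 * p.k_nuc_max * p.npf_density / p.k_cap0 + 10.0
    return float(optimize.brentq(balance, lo, hi, xtol=1e-10, rtol=1e-12))
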