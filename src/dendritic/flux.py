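"""Steady-state flux-balance analysis of force-clamp and TIRF measurements.

A branched actin network growing against a constant stress (AFM force
clamp) settles into linear height growth; the slope is the growth velocity.
Multiplying the steady-state density of a fluorescent component (actin,
capping protein, Arp2/3) by that velocity gives the per-network
incorporation flux of the component, and dividing by the relative density
of free barbed ends gives the per-filament rate.  At steady state the
network-level nucleation and capping rates must balance,

    R_cap = k_cap [CP] E = R_nucleate,

which rearranges to the free barbed-end density E = R_nucleate/(k_cap [CP]).
This module segments force-clamp traces into steady phases, computes the
velocities and normalized rates, fits exponential force responses, and
carries the small ancillary calculations (monomer consumption fraction,
network mesh size, diffusion-impact threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    DegenerateFitError,
    DomainError,
    FitFailureError,
    InsufficientDataError,
    NormalizationError,
    TimeOrderingError,
)

__all__ = [
    "AfmTrace",
    "IntensityTrace",
    "SteadySegment",
    "DecayFit",
    "find_steady_segments",
    "growth_velocity",
    "per_network_rate",
    "per_filament_rate",
    "barbed_end_density_steady_state",
    "fit_decay",
    "fit_linear",
    "mean_filament_length_ratio",
    "monomer_consumption_fraction",
    "mesh_size",
    "diffusion_threshold",
    "build_rate_table",
    "subtract_baseline",
]


def _check_time(time: np.ndarray) -> None:
    if time.size >= 2 and np.any(np.diff(time) <= 0):
        raise TimeOrderingError("time axis must be strictly increasing")


@dataclass(frozen=True)
class AfmTrace:
    """Force-clamp time series: time (s), height (µm), stress (Pa)."""

    time: np.ndarray
    height: np.ndarray
    stress: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        h = np.asarray(self.height, dtype=float)
        s = np.asarray(self.stress, dtype=float)
        if not (t.shape == h.shape == s.shape):
            raise DomainError("time, height and stress must have equal length")
        _check_time(t)
        if not np.all(np.isfinite(h)):
            raise DomainError("height must be finite")
        if np.any(s < 0):
            raise DomainError("stress must be >= 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "height", h)
        object.__setattr__(self, "stress", s)

    def __len__(self):
        return self.time.size


@dataclass(frozen=True)
class IntensityTrace:
    """Background-subtracted mean intensity of one channel vs time."""

    time: np.ndarray
    channel: str
    density: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        d = np.asarray(self.density, dtype=float)
        if t.shape != d.shape:
            raise DomainError("time and density must have equal length")
        _check_time(t)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "density", d)


@dataclass(frozen=True)
class SteadySegment:
    """One steady-growth phase of a force-clamp trace."""

    t_start: float
    t_end: float
    stress: float
    velocity: float  # µm/min
    r_squared: float

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise DomainError("t_end must exceed t_start")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise DomainError(f"r_squared outside [0,1]: {self.r_squared}")


def subtract_baseline(trace: IntensityTrace, lag_window: tuple[float, float]) -> IntensityTrace:
    """Subtract the mean pre-nucleation (lag-phase) signal from a channel.

    The NPF-bound fraction of the fluorescence is quantified during the lag
    phase before network nucleation and removed as a constant baseline;
    negative residuals are clipped to zero.
    """
    t0, t1 = lag_window
    mask = (trace.time >= t0) & (trace.time <= t1)
    if not mask.any():
        raise DomainError("lag window contains no samples")
    baseline = float(trace.density[mask].mean())
    return IntensityTrace(
        trace.time, trace.channel, np.clip(trace.density - baseline, 0.0, None)
    )


def _linfit(t: np.ndarray, h: np.ndarray) -> tuple[float, float]:
    """OLS slope and r² with a flat-data convention (r²=1 for an exact fit)."""
    slope, intercept = np.polyfit(t, h, 1)
    resid = h - (slope * t + intercept)
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.dot(h - h.mean(), h - h.mean()))
    if ss_tot <= 1e-30:
        r2 = 1.0 if ss_res <= 1e-30 else 0.0
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return float(slope), r2


def growth_velocity(time: np.ndarray, height: np.ndarray) -> float:
    """OLS slope of height vs time, converted to µm·min⁻¹."""
    time = np.asarray(time, dtype=float)
    height = np.asarray(height, dtype=float)
    if time.size < 3:
        raise InsufficientDataError("growth velocity needs >= 3 samples")
    _check_time(time)
    slope, _ = _linfit(time, height)
    return slope * 60.0


_SQRT2 = float(np.sqrt(2.0))


def _stress_blocks(stress: np.ndarray, tol_rel: float, tol_floor: float) -> list[tuple[int, int]]:
    """Contiguous index blocks of near-constant stress setpoint.

    A rolling median suppresses clamp noise; block boundaries are jumps of
    the smoothed stress exceeding the larger of the absolute floor, the
    relative tolerance and 6× the robust (MAD-based) noise scale.
    """
    n = stress.size
    if n < 3:
        return [(0, n)]
    w = min(5, n)
    pad = w // 2
    padded = np.pad(stress, pad, mode="edge")
    smooth = np.array(
        [np.median(padded[i:i + w]) for i in range(n)]
    )
    diffs = np.abs(np.diff(stress))
    noise = 1.4826 * float(np.median(diffs)) / _SQRT2 if diffs.size else 0.0
    blocks = []
    start = 0
    for i in range(1, n):
        level = max(abs(smooth[i]), abs(smooth[i - 1]))
        tol = max(tol_floor, tol_rel * level, 6.0 * noise)
        if abs(smooth[i] - smooth[i - 1]) > tol:
            blocks.append((start, i))
            start = i
    blocks.append((start, n))
    return blocks


def find_steady_segments(
    trace: AfmTrace,
    min_duration: float = 60.0,
    stress_tol: float = 0.02,
    r2_min: float = 0.99,
    stress_tol_floor: float = 1.0,
) -> list[SteadySegment]:
    """Detect maximal steady-growth windows in a force-clamp trace.

    The trace is first split into blocks of near-constant stress (within
    ``stress_tol`` relative to the block median, with an absolute floor
    ``stress_tol_floor`` Pa for zero-load holds).  Within each block the
    start is advanced past the post-setpoint adaptation transient until the
    height-vs-time linear fit reaches ``r2_min``; blocks shorter than
    ``min_duration`` (s) are dropped.  Returns non-overlapping segments in
    time order; an empty list when nothing qualifies.
    """
    if min_duration <= 0 or r2_min <= 0:
        raise DomainError("thresholds must be positive")
    if len(trace) == 0:
        raise DomainError("empty trace")
    segments: list[SteadySegment] = []
    for a, b in _stress_blocks(trace.stress, stress_tol, stress_tol_floor):
        if b - a < 3:
            continue
        t = trace.time[a:b]
        h = trace.height[a:b]
        if t[-1] - t[0] < min_duration:
            continue
        n = t.size
        step = max(1, n // 100)
        start = 0
        found = None
        while t[-1] - t[start] >= min_duration and n - start >= 3:
            slope, r2 = _linfit(t[start:], h[start:])
            if r2 >= r2_min:
                found = (start, slope, r2)
                break
            start += step
        if found is None:
            continue
        start, slope, r2 = found
        segments.append(
            SteadySegment(
                t_start=float(t[start]),
                t_end=float(t[-1]),
                stress=float(np.median(trace.stress[a:b])),
                velocity=slope * 60.0,
                r_squared=r2,
            )
        )
    return segments


def per_network_rate(
    mean_density: np.ndarray, velocity: np.ndarray, reference_flux: float
) -> np.ndarray:
    """Component flux (density × velocity) normalized to the reference load."""
    if reference_flux <= 0:
        raise NormalizationError(f"reference flux must be > 0, got {reference_flux}")
    return np.asarray(mean_density, dtype=float) * np.asarray(velocity, dtype=float) / reference_flux


def per_filament_rate(
    per_network: np.ndarray, barbed_end_density_rel: np.ndarray
) -> np.ndarray:
    """Per-network rate divided by the relative free barbed-end density."""
    e_rel = np.asarray(barbed_end_density_rel, dtype=float)
    if np.any(e_rel <= 0):
        raise DomainError("relative barbed-end density must be > 0")
    return np.asarray(per_network, dtype=float) / e_rel


def barbed_end_density_steady_state(
    r_nucleate: float, k_cap: float, cp_conc: float
) -> float:
    """Free barbed-end density E = R_nucleate / (k_cap [CP]), µm⁻².

    Follows from the steady-state balance R_cap = k_cap [CP] E = R_nucleate.
    """
    for name, v in (("r_nucleate", r_nucleate), ("k_cap", k_cap), ("cp_conc", cp_conc)):
        if v <= 0:
            raise DomainError(f"{name} must be > 0, got {v}")
    return r_nucleate / (k_cap * cp_conc)


@dataclass(frozen=True)
class DecayFit:
    """Exponential-decay fit result; decay constants ordered ascending."""

    amplitudes: np.ndarray
    decay_constants: np.ndarray
    r_squared: float
    residual: float


def _decay_model(x, *theta):
    n = len(theta) // 2
    amps = theta[:n]
    taus = theta[n:]
    y = np.zeros_like(x, dtype=float)
    for a, tau in zip(amps, taus):
        y = y + a * np.exp(-x / tau)
    return y


def fit_decay(x: np.ndarray, y: np.ndarray, n_components: int = 1) -> DecayFit:
    """Nonlinear least-squares fit of a 1- or 2-component exponential decay.

    Uses multi-start over log-spaced initial decay constants to escape the
    label-swap degeneracy of the two-component model; the returned decay
    constants are sorted ascending with their amplitudes.  Constant data
    raise :class:`DegenerateFitError` (no finite decay constant exists).
    """
    if n_components not in (1, 2):
        raise DomainError("n_components must be 1 or 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 * n_components + 1:
        raise InsufficientDataError(
            f"need >= {2 * n_components + 1} points for {n_components} component(s)"
        )
    if np.any(y <= 0):
        raise DomainError("rates must be > 0 for an exponential-decay fit")
    if np.ptp(y) <= 1e-12 * abs(y[0]):
        raise DegenerateFitError("constant response: decay constant is unbounded")

    span = np.ptp(x) if np.ptp(x) > 0 else 1.0
    tau_grid = np.geomspace(span / 50.0, span * 50.0, 6)
    best = None
    for tau0 in tau_grid:
        if n_components == 1:
            p0 = [y.max(), tau0]
        else:
            p0 = [y.max() / 2, y.max() / 2, tau0 / 5.0, tau0]
        try:
            popt, _ = optimize.curve_fit(
                _decay_model, x, y, p0=p0,
                bounds=(0.0, np.inf), maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = y - _decay_model(x, *popt)
        ssr = float(np.dot(resid, resid))
        if best is None or ssr < best[1]:
            best = (popt, ssr)
    if best is None:
        raise FitFailureError("exponential fit did not converge from any start")
    popt, ssr = best
    amps = np.asarray(popt[:n_components])
    taus = np.asarray(popt[n_components:])
    order = np.argsort(taus)
    ss_tot = float(np.dot(y - y.mean(), y - y.mean()))
    r2 = 1.0 - ssr / ss_tot if ss_tot > 0 else 1.0
    return DecayFit(
        amplitudes=amps[order],
        decay_constants=taus[order],
        r_squared=max(0.0, r2),
        residual=ssr,
    )


def fit_linear(x: np.ndarray, y: np.ndarray):
    """Linear force-response fit (slope, intercept, r, p, stderr)."""
    return stats.linregress(np.asarray(x, float), np.asarray(y, float))


def mean_filament_length_ratio(
    actin_density: np.ndarray,
    cp_density: np.ndarray,
    normalize: bool = False,
) -> np.ndarray:
    """CP:actin fluorescence ratio per load (inverse to mean filament length).

    With ``normalize=True`` the series is divided by its first (unloaded)
    entry.  A flat ratio across loads means load-invariant filament length.
    """
    actin = np.asarray(actin_density, dtype=float)
    cp = np.asarray(cp_density, dtype=float)
    if np.any(actin <= 0):
        raise DomainError("actin density must be > 0")
    if np.any(cp <= 0):
        raise DomainError("CP density must be > 0")
    ratio = cp / actin
    if normalize:
        ratio = ratio / ratio.flat[0]
    return ratio


def monomer_consumption_fraction(
    polymer_conc: float, network_volume: float, total_conc: float, total_volume: float
) -> float:
    """Fraction of the soluble actin pool consumed by the networks.

    (polymer µM × network volume) / (total µM × reaction volume); volumes in
    any common unit.
    """
    for name, v in (
        ("polymer_conc", polymer_conc),
        ("network_volume", network_volume),
        ("total_conc", total_conc),
        ("total_volume", total_volume),
    ):
        if v <= 0:
            raise DomainError(f"{name} must be > 0, got {v}")
    return (polymer_conc * network_volume) / (total_conc * total_volume)


def mesh_size(polymer_conc: float) -> float:
    """Network mesh size ζ = 1.47 / sqrt(C_A), µm for C_A in µM."""
    if polymer_conc <= 0:
        raise DomainError(f"polymer_conc must be > 0, got {polymer_conc}")
    return 1.47 / np.sqrt(polymer_conc)


def diffusion_threshold(zeta: float, factor: float = 0.4) -> float:
    """Stokes-radius threshold 0.4·ζ above which the mesh impedes diffusion.

    Same length unit as the supplied mesh size.
    """
    if zeta <= 0:
        raise DomainError(f"mesh size must be > 0, got {zeta}")
    return factor * zeta


def build_rate_table(
    stress: Sequence[float],
    density: dict[str, np.ndarray],
    velocity: np.ndarray,
    barbed_end_density_rel: np.ndarray,
    reference_stress: float = 25.0,
):
    """Normalized per-network and per-filament rates for each channel.

    Returns a pandas DataFrame ``stress_pa, channel, per_network_rate,
    per_filament_rate, barbed_end_density_rel`` with both rates exactly 1
    at the reference load.
    """
    import pandas as pd

    stress = np.asarray(stress, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    e_rel = np.asarray(barbed_end_density_rel, dtype=float)
    # measured segment stresses carry clamp noise: match the reference load
    # within 5% or 2 Pa, whichever is larger
    ref_idx = np.flatnonzero(
        np.abs(stress - reference_stress) <= max(0.05 * reference_stress, 2.0)
    )
    if ref_idx.size == 0:
        raise NormalizationError(
            f"no entry at the reference stress {reference_stress} Pa"
        )
    i_ref = int(ref_idx[0])
    rows = []
    for channel, dens in density.items():
        dens = np.asarray(dens, dtype=float)
        ref_flux = dens[i_ref] * velocity[i_ref]
        pnr = per_network_rate(dens, velocity, ref_flux)
        pfr = per_filament_rate(pnr, e_rel / e_rel[i_ref])
        for j in range(stress.size):
            rows.append(
                dict(
                    stress_pa=stress[j],
                    channel=channel,
                    per_network_rate=pnr[j],
                    per_filament_rate=pfr[j],
                    barbed_end_density_rel=e_rel[j] / e_rel[i_ref],
                )
            )
    return pd.DataFrame(rows)
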