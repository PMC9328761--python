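"""WH2-domain occupancy from donor-quenching (FRET) kinetics.

Surface-immobilized, donor-labeled NPF molecules are exposed to
quencher-labeled actin monomers at t = 0.  Monomers bind available WH2
domains and quench the donor with a fast rate k1; WH2 domains occupied by
filament barbed ends are *protected* and their donors decay only by slow
photobleaching (rate k2, measured independently in controls).  The donor
trace is therefore a two-exponential,

    I(t) = (1 − p)·exp(−k1·t) + p·exp(−k2·t),

with ``p`` the protected fraction.  Fitting with k2 clamped and comparing
the fast-phase amplitude I_FRET against a no-network reference (p = 0)
yields the fraction of WH2 domains occupied by barbed ends, and the
loaded/unloaded quotient its fold change under force.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import (
    DomainError,
    FitFailureError,
    NormalizationError,
    PhaseSeparationError,
    TimeOrderingError,
)

__all__ = [
    "QuenchCurve",
    "QuenchFit",
    "simulate_quench_curve",
    "fit_quench",
    "protected_fraction",
    "occupancy_fold_change",
]


@dataclass(frozen=True)
class QuenchCurve:
    """Donor fluorescence vs time after quencher addition (t = 0)."""

    time: np.ndarray
    donor_intensity: np.ndarray
    condition: str = "unspecified"  # no-network | unloaded | loaded

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.donor_intensity, dtype=float)
        if t.shape != y.shape:
            raise DomainError("time and intensity must have equal length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise TimeOrderingError("time must be strictly increasing")
        if np.any(y < 0):
            raise DomainError("donor intensity must be >= 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "donor_intensity", y)


@dataclass(frozen=True)
class QuenchFit:
    """Two-exponential fit with the bleaching rate k2 held fixed."""

    i_fret: float  # fast-phase amplitude
    k1: float  # fast (quenching) rate, s⁻¹
    i_bleach: float  # slow-phase amplitude
    k2: float  # bleaching rate, s⁻¹ (fixed)
    r_squared: float


def simulate_quench_curve(
    protected_fraction: float,
    k1: float,
    k2: float,
    noise_sd: float = 0.0,
    duration: float | None = None,
    dt: float = 0.1,
    seed: int | None = 0,
    condition: str = "unspecified",
) -> QuenchCurve:
    """Synthetic donor-quench curve for a given protected fraction.

    Unprotected donors (fraction 1 − p) decay by fast quenching,
    protected donors by bleaching only: I(t) = (1−p)e^(−k1 t) + p e^(−k2 t),
    plus Gaussian noise.  Default duration covers 8/k1 of the fast phase.
    """
    if not 0.0 <= protected_fraction <= 1.0:
        raise DomainError("protected_fraction must be in [0, 1]")
    if not k1 > k2 > 0:
        raise DomainError(f"need k1 > k2 > 0, got k1={k1}, k2={k2}")
    if duration is None:
        duration = 8.0 / k1
    t = np.arange(0.0, duration + dt / 2, dt)
    p = protected_fraction
    y = (1.0 - p) * np.exp(-k1 * t) + p * np.exp(-k2 * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + rng.normal(0.0, noise_sd, t.size), 0.0, None)
    return QuenchCurve(time=t, donor_intensity=y, condition=condition)


def fit_quench(curve: QuenchCurve, k2_fixed: float) -> QuenchFit:
    """Least-squares fit of I(t) = I_FRET·e^(−k1 t) + I_bleach·e^(−k2 t).

    The bleaching rate ``k2_fixed`` (determined in independent control
    experiments) is clamped; the free parameters are the two non-negative
    amplitudes and the fast rate k1.  Multi-start over log-spaced k1
    guesses; a fitted k1 <= k2 raises :class:`PhaseSeparationError` (the
    fast and slow phases could not be separated).
    """
    if k2_fixed <= 0:
        raise DomainError(f"k2_fixed must be > 0, got {k2_fixed}")
    t = curve.time
    y = curve.donor_intensity

    def model(tt, i_fret, k1, i_bleach):
        return i_fret * np.exp(-k1 * tt) + i_bleach * np.exp(-k2_fixed * tt)

    span = max(t[-1] - t[0], 1e-12)
    best = None
    for k1_0 in np.geomspace(2.0 / span, 200.0 / span, 6):
        try:
            popt, _ = optimize.curve_fit(
                model, t, y,
                p0=[max(y[0] - y[-1], 0.1 * y[0]), k1_0, max(y[-1], 1e-6)],
                bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=20000, ftol=1e-14, xtol=1e-14, gtol=1e-14,
            )
        except (RuntimeError, ValueError):
            continue
        resid = y - model(t, *popt)
        ssr = float(np.dot(resid, resid))
        if best is None or ssr < best[1]:
            best = (popt, ssr)
    if best is None:
        raise FitFailureError("quench fit did not converge from any start")
    (i_fret, k1, i_bleach), ssr = best
    if k1 <= k2_fixed:
        raise PhaseSeparationError(
            f"fitted k1 = {k1:.4g} <= fixed k2 = {k2_fixed:.4g}: "
            "fast and slow phases are not separable"
        )
    if t[-1] - t[0] < 3.0 / k1:
        warnings.warn(
            "curve spans less than 3/k1 of the fast phase; amplitude may be biased"
        )
    ss_tot = float(np.dot(y - y.mean(), y - y.mean()))
    r2 = 1.0 - ssr / ss_tot if ss_tot > 0 else 1.0
    return QuenchFit(
        i_fret=float(i_fret), k1=float(k1), i_bleach=float(i_bleach),
        k2=k2_fixed, r_squared=max(0.0, r2),
    )


def protected_fraction(fit_sample: QuenchFit, fit_no_network: QuenchFit) -> float:
    """Occupied-WH2 fraction p = 1 − I_FRET(sample)/I_FRET(no network).

    All WH2 domains are assumed quenchable in the no-network reference, so
    the relative loss of fast-phase amplitude measures the fraction
    shielded by barbed ends.  Estimates outside [0, 1] are clipped with a
    warning (noise can push the ratio past the ideal range).
    """
    if fit_no_network.i_fret <= 0:
        raise NormalizationError("reference I_FRET must be > 0")
    p = 1.0 - fit_sample.i_fret / fit_no_network.i_fret
    if not 0.0 <= p <= 1.0:
        warnings.warn(f"protected fraction {p:.4g} outside [0, 1]; clipping")
        p = min(max(p, 0.0), 1.0)
    return p


def occupancy_fold_change(p_loaded: float, p_unloaded: float) -> float:
    """Fold increase of the protected fraction under load."""
    if p_unloaded <= 0:
        raise DomainError("unloaded protected fraction must be > 0")
    return p_loaded / p_unloaded
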