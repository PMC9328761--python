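"""Brownian-ratchet rate laws for filament elongation and capping under load.

A filament pushing against a surface can accept a new subunit (actin monomer
or capping protein) only when thermal fluctuations transiently open a gap of
size ``delta`` between the barbed end and the surface.  The probability of
such a gap decays exponentially with the mechanical work needed to open it,
so the insertion rate constant carries a Boltzmann factor

    B(f, delta, sin_theta) = exp(-f * delta * sin_theta / kBT)

where ``f`` is the force borne by that filament (pN), ``delta`` the gap size
(nm), ``theta`` the filament contact angle to the surface, and ``kBT`` the
thermal energy (pN·nm).  Monomeric actin and wildtype capping protein both
need a 2.7 nm gap, which is why elongation and capping share a force
response; an engineered "bulky" capping protein needs a larger gap and so
caps relatively more slowly under load.

Two network-level quantities feed the law: the force per filament comes from
dividing the growth stress over the free barbed ends that share the load
(plus a small internal tethering force from transient NPF/barbed-end links),
and the effective contact angle is estimated from the barbed-end density and
the polymeric-actin density.  The single free parameter of the model, the
tethering force, is recovered here by least squares from wildtype/bulky
incorporation-ratio data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import (
    ConfigurationError,
    DomainError,
    GeometricInconsistencyError,
    NonIdentifiableError,
)

__all__ = [
    "PhysicalConstants",
    "RatchetParams",
    "NetworkState",
    "TetherFit",
    "boltzmann_step_factor",
    "sin_theta_from_network",
    "force_per_filament",
    "effective_force",
    "relative_insertion_rate",
    "wt_bulky_ratio",
    "fit_tether_force",
]

#: µM -> molecules·µm⁻³ (Avogadro's number scaled to these units)
MOLARITY_TO_DENSITY = 602.2


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants and geometry shared by all rate laws.

    Parameters
    ----------
    kBT : float
        Thermal energy in pN·nm.  Default 4.114 (T = 298 K).
    molarity_to_density : float
        Conversion from µM to molecules·µm⁻³ (fixed, 602.2).
    subunit_rise_nm : float
        Filament length added per subunit, nm.  2.7 nm, equal to the gap
        size an incoming monomer requires.
    """

    kBT: float = 4.114
    molarity_to_density: float = MOLARITY_TO_DENSITY
    subunit_rise_nm: float = 2.7

    def __post_init__(self):
        if self.kBT <= 0:
            raise DomainError(f"kBT must be > 0, got {self.kBT}")
        if self.subunit_rise_nm <= 0:
            raise DomainError(
                f"subunit_rise_nm must be > 0, got {self.subunit_rise_nm}"
            )

    @property
    def subunit_rise_um(self) -> float:
        return self.subunit_rise_nm * 1e-3


@dataclass(frozen=True)
class RatchetParams:
    """Gap sizes and tether force governing force-dependent insertion.

    ``delta_actin`` and ``delta_cap_wt`` default to 2.7 nm (monomer and
    wildtype capping protein need the same gap).  ``delta_cap_bulky``
    defaults to twice the wildtype gap as a configurable placeholder for the
    engineered larger variant.  ``f_tether`` is the characteristic internal
    friction-like force per filament from transient NPF/barbed-end links; it
    adds to the external per-filament load at every stress, including zero.
    ``reference_stress`` is the load whose state normalizes relative rates.
    """

    delta_actin: float = 2.7
    delta_cap_wt: float = 2.7
    delta_cap_bulky: float = 5.4
    f_tether: float = 0.3
    reference_stress: float = 25.0
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    def __post_init__(self):
        for name in ("delta_actin", "delta_cap_wt", "delta_cap_bulky"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.delta_cap_bulky < self.delta_cap_wt:
            raise DomainError(
                "delta_cap_bulky must be >= delta_cap_wt "
                f"({self.delta_cap_bulky} < {self.delta_cap_wt})"
            )
        if self.f_tether < 0:
            raise DomainError(f"f_tether must be >= 0, got {self.f_tether}")


@dataclass(frozen=True)
class NetworkState:
    """Per-load snapshot of a growing network.

    stress : Pa (≡ pN·µm⁻²), applied growth stress.
    barbed_end_density : µm⁻², free (uncapped) barbed ends per area.
    polymer_conc : µM, polymeric actin concentration near the surface.
    velocity : µm·min⁻¹, network growth velocity (NaN when unknown).
    component_density : per-channel normalized TIRF density, optional.
    """

    stress: float
    barbed_end_density: float
    polymer_conc: float
    velocity: float = float("nan")
    component_density: dict | None = None

    def __post_init__(self):
        if self.stress < 0:
            raise DomainError(f"stress must be >= 0, got {self.stress}")
        if self.barbed_end_density <= 0:
            raise DomainError(
                f"barbed_end_density must be > 0, got {self.barbed_end_density}"
            )
        if self.polymer_conc <= 0:
            raise DomainError(f"polymer_conc must be > 0, got {self.polymer_conc}")


def boltzmann_step_factor(
    f_eff: float,
    delta: float,
    sin_theta: float,
    constants: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Gap-opening probability factor exp(-f·δ·sinθ / kBT), in (0, 1].

    Equals 1 iff the effective force is zero; strictly decreasing in each of
    ``f_eff`` (pN), ``delta`` (nm) and ``sin_theta``.
    """
    if f_eff < 0:
        raise DomainError(f"f_eff must be >= 0, got {f_eff}")
    if delta <= 0:
        raise DomainError(f"delta must be > 0, got {delta}")
    if not (0.0 < sin_theta <= 1.0):
        raise DomainError(f"sin_theta must be in (0, 1], got {sin_theta}")
    return math.exp(-f_eff * delta * sin_theta / constants.kBT)


#: float slack on the geometric bound sinθ <= 1 (see sin_theta_from_network)
_SIN_THETA_SLACK = 1e-3


def sin_theta_from_network(
    barbed_end_density: float,
    polymer_conc: float,
    constants: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Effective sin of the filament contact angle from network densities.

    The polymeric actin concentration sets a filament length per volume
    L_v = C_A · 602.2 · rise (µm of filament per µm³).  A surface pierced by
    ``E`` ends per µm² of filaments at angle θ intercepts length E/sinθ per
    area per unit depth, so sinθ = E / L_v.  Values in (1, 1+1e-3] are
    clamped to 1 (filaments perpendicular to the surface saturate the
    bound); larger ratios are a hard geometric inconsistency.
    """
    if barbed_end_density <= 0:
        raise DomainError(
            f"barbed_end_density must be > 0, got {barbed_end_density}"
        )
    if polymer_conc <= 0:
        raise DomainError(f"polymer_conc must be > 0, got {polymer_conc}")
    length_per_volume = (
        polymer_conc * constants.molarity_to_density * constants.subunit_rise_um
    )
    ratio = barbed_end_density / length_per_volume
    if ratio > 1.0 + _SIN_THETA_SLACK:
        raise GeometricInconsistencyError(
            f"barbed_end_density/L_v = {ratio:.4g} > 1: more ends per area "
            "than the filament length density allows"
        )
    return min(ratio, 1.0)


def force_per_filament(stress: float, barbed_end_density: float) -> float:
    """External load per free barbed end, pN (1 Pa = 1 pN·µm⁻²).

    The total stress on the network area is shared equally over the free
    barbed ends pushing the surface.
    """
    if stress < 0:
        raise DomainError(f"stress must be >= 0, got {stress}")
    if barbed_end_density <= 0:
        raise DomainError(
            f"barbed_end_density must be > 0, got {barbed_end_density}"
        )
    return stress / barbed_end_density


def effective_force(state: NetworkState, f_tether: float) -> float:
    """Per-filament load plus the internal tethering force, pN."""
    return force_per_filament(state.stress, state.barbed_end_density) + f_tether


def _state_factor(state: NetworkState, delta: float, params: RatchetParams) -> float:
    f_eff = effective_force(state, params.f_tether)
    s = sin_theta_from_network(
        state.barbed_end_density, state.polymer_conc, params.constants
    )
    return boltzmann_step_factor(f_eff, delta, s, params.constants)


def relative_insertion_rate(
    state_load: NetworkState,
    state_ref: NetworkState,
    delta: float,
    params: RatchetParams,
) -> float:
    """Insertion rate constant at load relative to the reference state.

    Both states contribute a Boltzmann factor evaluated at their own
    per-filament force (external share + tether) and contact angle; the
    ratio is 1 for identical states.
    """
    return _state_factor(state_load, delta, params) / _state_factor(
        state_ref, delta, params
    )


def _find_reference(states: Sequence[NetworkState], params: RatchetParams) -> NetworkState:
    for s in states:
        if math.isclose(s.stress, params.reference_stress, abs_tol=1e-9):
            return s
    raise ConfigurationError(
        f"no state at the reference stress {params.reference_stress} Pa "
        f"(available: {[s.stress for s in states]})"
    )


def wt_bulky_ratio(
    states: Sequence[NetworkState], params: RatchetParams
) -> np.ndarray:
    """Predicted wildtype/bulky CP incorporation ratio per load.

    For each state the normalized (to the reference load) insertion rates
    for the wildtype and bulky gap sizes are formed and their quotient
    returned, one value per input state.  With equal gap sizes the ratio is
    identically 1; with a larger bulky gap it is >= 1 and grows with the
    force·sinθ product.
    """
    ref = _find_reference(states, params)
    out = np.empty(len(states))
    for i, s in enumerate(states):
        r_wt = relative_insertion_rate(s, ref, params.delta_cap_wt, params)
        r_bulky = relative_insertion_rate(s, ref, params.delta_cap_bulky, params)
        out[i] = r_wt / r_bulky
    return out


@dataclass(frozen=True)
class TetherFit:
    """Result of the single-parameter tethering-force fit."""

    f_tether: float
    ci_low: float
    ci_high: float
    chi2: float
    bootstrap: np.ndarray


def _ratio_model(
    f_tether: float, states: Sequence[NetworkState], params: RatchetParams
) -> np.ndarray:
    return wt_bulky_ratio(states, replace(params, f_tether=f_tether))


def fit_tether_force(
    stress: np.ndarray,
    ratio: np.ndarray,
    error: np.ndarray,
    states: Sequence[NetworkState],
    params: RatchetParams,
    f_max: float = 10.0,
    n_boot: int = 500,
    seed: int | None = 0,
) -> TetherFit:
    """Least-squares fit of the tethering force to wt/bulky ratio data.

    All other model inputs (gap sizes, per-load network states) are held
    fixed; only ``f_tether >= 0`` is free.  ``states`` must contain one
    state per data stress plus the reference-load state.  The confidence
    interval is a parametric bootstrap: synthetic datasets are drawn from
    the fitted model with the per-point Gaussian errors and refit, and the
    2.5/97.5 percentiles of the refits reported.
    """
    stress = np.asarray(stress, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    error = np.asarray(error, dtype=float)
    if stress.size < 3:
        raise NonIdentifiableError("need >= 3 loads to constrain the tether force")
    if np.ptp(stress) == 0:
        raise NonIdentifiableError("all loads equal: tether force not identifiable")
    if np.any(error <= 0):
        raise DomainError("all ratio errors must be > 0")

    by_stress = {}
    for s in states:
        by_stress[round(s.stress, 9)] = s
    try:
        data_states = [by_stress[round(x, 9)] for x in stress]
    except KeyError as exc:
        raise ConfigurationError(f"no network state for stress {exc} Pa") from exc
    # the reference state must ride along for normalization
    ref = _find_reference(states, params)
    model_states = list(data_states)
    if ref not in model_states:
        model_states.append(ref)

    def predict(f_t: float) -> np.ndarray:
        full = _ratio_model(f_t, model_states, params)
        return full[: len(data_states)]

    def chi2(f_t: float) -> float:
        resid = (predict(f_t) - ratio) / error
        return float(np.dot(resid, resid))

    def solve(y: np.ndarray) -> float:
        res = minimize_scalar(
            lambda f: float(np.sum(((predict(f) - y) / error) ** 2)),
            bounds=(0.0, f_max),
            method="bounded",
            options={"xatol": 1e-8},
        )
        return float(res.x)

    est = solve(ratio)
    model_at_est = predict(est)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        y_b = model_at_est + rng.normal(0.0, error)
        boots[b] = solve(y_b)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return TetherFit(
        f_tether=est, ci_low=float(lo), ci_high=float(hi),
        chi2=chi2(est), bootstrap=boots,
    )
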