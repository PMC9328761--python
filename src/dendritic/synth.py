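"""Synthetic data emulating AFM force-clamp and TIRF measurements.

Every input the analysis pipeline consumes can be generated here with the
statistical structure the estimators assume: stepwise constant-stress AFM
traces with exponential adaptation transients and Gaussian height noise,
per-channel TIRF density plateaus, monotonically rising barbed-end
densities, and wildtype/bulky capping-protein incorporation ratios drawn
from the ratchet model with multiplicative noise.

The default force-response curves are smooth parametric stand-ins shaped
to the measured phenomenology — per-network fluxes decline linearly to
~50% at the ~1200 Pa stall, component densities rise saturably, the
barbed-end density reaches 3.3× the unloaded value at the 1020 Pa
high-load setpoint, and the unloaded velocity is 7.3 µm/min — not curves
fitted to any particular dataset.  All generators are deterministic under
a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .flux import AfmTrace, IntensityTrace
from .ratchet import NetworkState, RatchetParams, wt_bulky_ratio

__all__ = [
    "ForceResponse",
    "GeneratorConfig",
    "gen_afm_trace",
    "gen_intensity_traces",
    "gen_barbed_end_series",
    "gen_ratio_dataset",
    "network_states",
]

CHANNELS = ("actin", "CP", "Arp2/3")


@dataclass(frozen=True)
class ForceResponse:
    """Parametric stress dependence of velocity, densities and barbed ends.

    unloaded_velocity : µm/min at zero load (default 7.3).
    flux_decline_per_pa : relative per-network flux lost per Pa; the
        default 0.5/1200 reaches 50% at the 1200 Pa stall-proximal stress.
    density_amp, density_k : saturating rise of component density,
        density_rel(σ) = 1 + amp·σ/(σ+k) (all channels share it, so
        network stoichiometry is load-invariant).
    e_amp, e_k : same form for the free barbed-end density; the defaults
        reach 3.3× at the 1020 Pa high-load setpoint.
    """

    unloaded_velocity: float = 7.3
    flux_decline_per_pa: float = 0.5 / 1200.0
    density_amp: float = 1.6
    density_k: float = 350.0
    e_amp: float = 2.3 * (1020.0 + 400.0) / 1020.0  # 1 + e_amp·1020/(1020+e_k) = 3.3
    e_k: float = 400.0
    flux_floor: float = 0.02

    def flux_rel(self, stress):
        return np.maximum(1.0 - self.flux_decline_per_pa * np.asarray(stress, float),
                          self.flux_floor)

    def density_rel(self, stress):
        s = np.asarray(stress, float)
        return 1.0 + self.density_amp * s / (s + self.density_k)

    def velocity(self, stress):
        """µm/min; flux = density × velocity fixes the velocity decline."""
        return self.unloaded_velocity * self.flux_rel(stress) / self.density_rel(stress)

    def e_rel(self, stress):
        s = np.asarray(stress, float)
        return 1.0 + self.e_amp * s / (s + self.e_k)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic measurement generators.

    stress_steps : [(stress Pa, hold s), ...] force-clamp staircase.
    adaptation_tau : s, exponential relaxation into each new steady phase.
    sample_dt : s, acquisition interval.
    height_noise : µm (Gaussian, default 10 nm), stress_noise : Pa,
    intensity_noise : relative per-channel Gaussian noise.
    e0 : µm⁻² unloaded free barbed-end density; polymer_conc0 : µM
        unloaded polymeric actin — together they set the unloaded contact
        angle of the ratchet model.
    """

    seed: int = 0
    stress_steps: tuple = ((0.0, 600.0), (25.0, 600.0), (255.0, 600.0),
                           (510.0, 600.0), (1020.0, 600.0))
    response: ForceResponse = field(default_factory=ForceResponse)
    adaptation_tau: float = 15.0
    sample_dt: float = 1.0
    height_noise: float = 0.010
    stress_noise: float = 1.0
    intensity_noise: float = 0.02
    e0: float = 150.0
    polymer_conc0: float = 150.0

    def __post_init__(self):
        if self.adaptation_tau <= 0 or self.sample_dt <= 0:
            raise DomainError("adaptation_tau and sample_dt must be > 0")
        for v in (self.height_noise, self.stress_noise, self.intensity_noise):
            if v < 0:
                raise DomainError("noise levels must be >= 0")
        if not self.stress_steps:
            raise DomainError("need at least one stress step")


def _velocity_profile(config: GeneratorConfig):
    """Per-sample instantaneous velocity (µm/s) and setpoint stress."""
    resp = config.response
    dt = config.sample_dt
    times, vels, stresses = [], [], []
    t0 = 0.0
    v_prev = resp.velocity(config.stress_steps[0][0]) / 60.0
    for sigma, hold in config.stress_steps:
        v_target = float(resp.velocity(sigma)) / 60.0
        n = int(round(hold / dt))
        tt = np.arange(n) * dt
        v = v_target + (v_prev - v_target) * np.exp(-tt / config.adaptation_tau)
        times.append(tt + t0)
        vels.append(v)
        stresses.append(np.full(n, float(sigma)))
        t0 += n * dt
        v_prev = float(v[-1])
    return np.concatenate(times), np.concatenate(vels), np.concatenate(stresses)


def gen_afm_trace(config: GeneratorConfig) -> AfmTrace:
    """Force-clamp trace: piecewise-linear height growth with transients.

    Each setpoint starts with an exponential relaxation of the velocity
    toward the steady value for that stress (time constant
    ``adaptation_tau``); height is the integral of the velocity, with
    Gaussian measurement noise on height and on the clamped stress.
    """
    rng = np.random.default_rng(config.seed)
    t, v, sigma = _velocity_profile(config)
    height = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(t))])
    if config.height_noise > 0:
        height = height + rng.normal(0.0, config.height_noise, t.size)
    if config.stress_noise > 0:
        sigma = np.clip(sigma + rng.normal(0.0, config.stress_noise, t.size), 0.0, None)
    return AfmTrace(time=t, height=height, stress=sigma)


def gen_intensity_traces(
    config: GeneratorConfig, include_control: bool = True
) -> dict[str, IntensityTrace]:
    """Per-channel TIRF density traces aligned with the AFM trace.

    Densities plateau at density_rel(σ) per step with the shared
    adaptation transient and channel-specific Gaussian noise.  With
    ``include_control`` a ``control`` channel emulating an adjacent
    unloaded network (constant density within noise) is added.
    """
    rng = np.random.default_rng(config.seed + 1)
    resp = config.response
    dt = config.sample_dt
    t_all, _, _ = _velocity_profile(config)
    dens = []
    t0 = 0.0
    d_prev = float(resp.density_rel(config.stress_steps[0][0]))
    for sigma, hold in config.stress_steps:
        d_target = float(resp.density_rel(sigma))
        n = int(round(hold / dt))
        tt = np.arange(n) * dt
        dens.append(d_target + (d_prev - d_target) * np.exp(-tt / config.adaptation_tau))
        t0 += n * dt
        d_prev = float(dens[-1][-1])
    density = np.concatenate(dens)
    out = {}
    for channel in CHANNELS:
        noisy = density.copy()
        if config.intensity_noise > 0:
            noisy = np.clip(
                noisy * (1.0 + rng.normal(0.0, config.intensity_noise, noisy.size)),
                0.0, None,
            )
        out[channel] = IntensityTrace(time=t_all, channel=channel, density=noisy)
    if include_control:
        ctrl = np.ones_like(density)
        if config.intensity_noise > 0:
            ctrl = np.clip(
                ctrl * (1.0 + rng.normal(0.0, config.intensity_noise, ctrl.size)),
                0.0, None,
            )
        out["control"] = IntensityTrace(time=t_all, channel="control", density=ctrl)
    return out


def gen_barbed_end_series(
    config: GeneratorConfig, stresses: Sequence[float] | None = None
) -> pd.DataFrame:
    """Relative free barbed-end density per stress (monotone increasing).

    Normalized to the unloaded value; the default response reaches 3.3×
    at the 1020 Pa setpoint.
    """
    if stresses is None:
        stresses = [s for s, _ in config.stress_steps]
    s = np.asarray(stresses, dtype=float)
    return pd.DataFrame({"stress_pa": s, "e_rel": config.response.e_rel(s)})


def network_states(
    config: GeneratorConfig, stresses: Sequence[float] | None = None
) -> list[NetworkState]:
    """Ratchet-model network states for a list of loads.

    Barbed-end density follows e0·e_rel(σ); the polymeric actin
    concentration scales with the component density, so the effective
    contact angle rises with load as observed.
    """
    if stresses is None:
        stresses = [s for s, _ in config.stress_steps]
    resp = config.response
    states = []
    for s in stresses:
        states.append(
            NetworkState(
                stress=float(s),
                barbed_end_density=config.e0 * float(resp.e_rel(s)),
                polymer_conc=config.polymer_conc0 * float(resp.density_rel(s)),
                velocity=float(resp.velocity(s)),
            )
        )
    return states


def gen_ratio_dataset(
    states: Sequence[NetworkState],
    params: RatchetParams,
    noise_cv: float = 0.05,
    n_replicates: int = 100,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Wildtype/bulky incorporation-ratio measurements per load.

    The ratchet model supplies the true ratio at each state; each of
    ``n_replicates`` replicate networks observes it with multiplicative
    log-normal noise (CV ``noise_cv``), and the per-load mean and standard
    error are reported — mirroring replicate-averaged intensity-ratio
    measurements.  With ``noise_cv=0`` the table is exact and the error
    column falls back to a nominal 1% of the ratio.
    """
    truth = wt_bulky_ratio(states, params)
    stresses = np.array([s.stress for s in states])
    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma_log = np.sqrt(np.log1p(noise_cv**2))
        draws = truth[:, None] * rng.lognormal(
            -0.5 * sigma_log**2, sigma_log, size=(truth.size, n_replicates)
        )
        mean = draws.mean(axis=1)
        err = draws.std(axis=1, ddof=1) / np.sqrt(n_replicates)
    else:
        mean = truth
        err = 0.01 * truth
    return pd.DataFrame({"stress_pa": stresses, "ratio": mean, "error": err})
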