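"""Brownian-ratchet rate laws: hand-evaluated oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendritic import (
    GeneratorConfig,
    NetworkState,
    PhysicalConstants,
    RatchetParams,
    boltzmann_step_factor,
    force_per_filament,
    network_states,
    relative_insertion_rate,
    sin_theta_from_network,
    wt_bulky_ratio,
)
from dendritic.errors import (
    ConfigurationError,
    DomainError,
    GeometricInconsistencyError,
    NonIdentifiableError,
)
from dendritic.ratchet import fit_tether_force
from dendritic.synth import gen_ratio_dataset

KBT = 4.114


class TestBoltzmannFactor:
    @pytest.mark.parametrize(
        "f,delta,sin_theta,expected",
        [
            (0.0, 2.7, 0.5, 1.0),  # zero-force identity
            (KBT / 2.7, 2.7, 1.0, math.exp(-1.0)),  # exponent −1 by construction
            (1.0, 2.7, 0.6, math.exp(-1.0 * 2.7 * 0.6 / KBT)),  # ≈0.6745, hand oracle
        ],
    )
    def test_values(self, f, delta, sin_theta, expected):
        assert boltzmann_step_factor(f, delta, sin_theta) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(f_eff=-1.0, delta=2.7, sin_theta=0.5), "f_eff"),
            (dict(f_eff=1.0, delta=-2.7, sin_theta=0.5), "delta"),
            (dict(f_eff=1.0, delta=2.7, sin_theta=0.0), "sin_theta"),
            (dict(f_eff=1.0, delta=2.7, sin_theta=1.5), "sin_theta"),
        ],
    )
    def test_domain_errors_name_argument(self, kwargs, match):
        with pytest.raises(DomainError, match=match):
            boltzmann_step_factor(**kwargs)

    @settings(deadline=None, derandomize=True)
    @given(
        f=st.floats(0.0, 20.0),
        delta=st.floats(0.1, 10.0),
        s=st.floats(0.01, 1.0),
    )
    def test_bounded_and_loglinear(self, f, delta, s):
        b = boltzmann_step_factor(f, delta, s)
        assert 0.0 < b <= 1.0
        if b == 1.0:
            # only a vanishing mechanical work leaves the factor at 1
            assert f * delta * s / KBT < 1e-12
        # log-factor exactly linear in each argument
        assert math.log(b) == pytest.approx(-f * delta * s / KBT, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(f=st.floats(0.1, 10.0), delta=st.floats(0.5, 5.0), s=st.floats(0.05, 0.95))
    def test_strictly_decreasing(self, f, delta, s):
        b = boltzmann_step_factor(f, delta, s)
        assert boltzmann_step_factor(f * 1.1, delta, s) < b
        assert boltzmann_step_factor(f, delta * 1.1, s) < b
        assert boltzmann_step_factor(f, delta, min(s * 1.1, 1.0)) < b


class TestSinTheta:
    def test_perpendicular_saturation(self):
        # E = C_A·602.2·0.0027 pins filaments perpendicular: sinθ = 1
        for ca in (50.0, 150.0, 1000.0):
            e = ca * 602.2 * 0.0027
            assert sin_theta_from_network(e, ca) == 1.0

    def test_unit_conversion_oracle(self):
        # 150 / (150·602.2·0.0027) computed by hand
        assert sin_theta_from_network(150.0, 150.0) == pytest.approx(
            150.0 / (150.0 * 602.2 * 0.0027), rel=1e-12
        )

    def test_geometric_inconsistency(self):
        with pytest.raises(GeometricInconsistencyError):
            sin_theta_from_network(500.0, 150.0)

    @settings(deadline=None, derandomize=True)
    @given(e=st.floats(1.0, 200.0), ca=st.floats(130.0, 2000.0))
    def test_never_exceeds_one(self, e, ca):
        assert 0.0 < sin_theta_from_network(e, ca) <= 1.0

    def test_composition_monotone_in_end_density(self):
        # more ends -> steeper angle -> smaller gap factor at fixed force
        factors = [
            boltzmann_step_factor(2.0, 2.7, sin_theta_from_network(e, 300.0))
            for e in (50.0, 100.0, 200.0, 400.0)
        ]
        assert all(a > b for a, b in zip(factors, factors[1:]))


class TestForcePerFilament:
    @pytest.mark.parametrize(
        "stress,e,expected", [(0.0, 100.0, 0.0), (1020.0, 1020.0, 1.0), (1276.0, 400.0, 3.19)]
    )
    def test_division(self, stress, e, expected):
        assert force_per_filament(stress, e) == pytest.approx(expected)

    def test_zero_density_error(self):
        with pytest.raises(DomainError):
            force_per_filament(100.0, 0.0)


def _state(stress, e, ca):
    return NetworkState(stress=stress, barbed_end_density=e, polymer_conc=ca)


class TestRelativeInsertionRate:
    def test_identity_for_identical_states(self):
        s = _state(100.0, 200.0, 200.0)
        p = RatchetParams(f_tether=0.3)
        assert relative_insertion_rate(s, s, 2.7, p) == pytest.approx(1.0, rel=1e-12)

    def test_reduces_to_boltzmann_factor(self):
        # tether off, reference unloaded with the same angle: plain gap factor
        ca = 1.0 / (602.2 * 0.0027) / 0.6  # sinθ = 0.6 at E = 1
        load = _state(1.0, 1.0, ca)  # f = 1 pN
        ref = _state(0.0, 1.0, ca)
        p = RatchetParams(f_tether=0.0)
        assert relative_insertion_rate(load, ref, 2.7, p) == pytest.approx(
            math.exp(-1.0 * 2.7 * 0.6 / KBT), rel=1e-9
        )

    def test_delta_doubling_squares_ratio(self):
        load = _state(500.0, 250.0, 300.0)
        ref = _state(25.0, 160.0, 200.0)
        p = RatchetParams()
        r1 = relative_insertion_rate(load, ref, 2.7, p)
        r2 = relative_insertion_rate(load, ref, 5.4, p)
        assert r2 == pytest.approx(r1**2, rel=1e-9)


class TestWtBulkyRatio:
    def test_equal_gaps_identically_one(self):
        states = network_states(GeneratorConfig(), [0, 25, 255, 510, 1020])
        p = RatchetParams(delta_cap_bulky=2.7)
        assert wt_bulky_ratio(states, p) == pytest.approx(np.ones(5), abs=1e-12)

    def test_reference_normalization(self):
        states = network_states(GeneratorConfig(), [0, 25, 510])
        r = wt_bulky_ratio(states, RatchetParams())
        assert r[1] == pytest.approx(1.0, abs=1e-12)

    def test_hand_evaluated_point(self):
        # f_eff = 1 pN, sinθ = 0.6, δ 2.7 vs 5.4, ref at zero force
        ca = 1.0 / (602.2 * 0.0027) / 0.6
        states = [_state(0.0, 1.0, ca), _state(1.0, 1.0, ca)]
        p = RatchetParams(f_tether=0.0, reference_stress=0.0)
        r = wt_bulky_ratio(states, p)
        assert r[1] == pytest.approx(math.exp(1.0 * 2.7 * 0.6 / KBT), rel=1e-9)

    def test_monotone_when_bulky_larger(self):
        states = network_states(GeneratorConfig(), [25, 150, 500, 1000, 1300])
        r = wt_bulky_ratio(states, RatchetParams())
        assert np.all(np.diff(r) > 0)
        assert np.all(r >= 1.0 - 1e-12)

    def test_missing_reference_raises(self):
        states = network_states(GeneratorConfig(), [0, 510])
        with pytest.raises(ConfigurationError):
            wt_bulky_ratio(states, RatchetParams(reference_stress=25.0))


class TestFitTetherForce:
    STRESSES = [0, 25, 150, 300, 510, 750, 1020, 1300]

    def _states(self):
        return network_states(GeneratorConfig(), self.STRESSES)

    @pytest.mark.parametrize("truth", [0.0, 0.3])
    def test_noise_free_recovery(self, truth):
        states = self._states()
        gen = RatchetParams(f_tether=truth)
        tab = gen_ratio_dataset(states, gen, noise_cv=0.0)
        fit = fit_tether_force(
            tab.stress_pa, tab.ratio, tab.error, states, gen, n_boot=20
        )
        assert fit.f_tether == pytest.approx(truth, rel=1e-6, abs=1e-6)

    def test_noisy_recovery_ci_coverage(self):
        """Bootstrap CI covers the generating tether force in >=90% of runs."""
        states = self._states()
        gen = RatchetParams(f_tether=0.3)
        covered = 0
        n_sim = 12
        for seed in range(n_sim):
            tab = gen_ratio_dataset(states, gen, noise_cv=0.05, n_replicates=100, seed=seed)
            fit = fit_tether_force(
                tab.stress_pa, tab.ratio, tab.error, states, gen,
                n_boot=200, seed=seed,
            )
            covered += fit.ci_low <= 0.3 <= fit.ci_high
        assert covered >= 0.9 * n_sim - 1  # allow one unlucky draw around 90%

    def test_degenerate_loads_not_identifiable(self):
        states = network_states(GeneratorConfig(), [25])
        with pytest.raises(NonIdentifiableError):
            fit_tether_force(
                np.array([25.0, 25.0, 25.0]),
                np.ones(3),
                np.full(3, 0.01),
                states * 3,
                RatchetParams(),
            )


class TestParamValidation:
    def test_constants_invariants(self):
        with pytest.raises(DomainError):
            PhysicalConstants(kBT=-1.0)
        with pytest.raises(DomainError):
            RatchetParams(delta_cap_bulky=1.0)  # smaller than wildtype gap
        with pytest.raises(DomainError):
            NetworkState(stress=-1.0, barbed_end_density=1.0, polymer_conc=1.0)
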