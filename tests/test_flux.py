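"""Flux-balance pipeline: segment detection, rates, fits, worked examples."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendritic import (
    AfmTrace,
    barbed_end_density_steady_state,
    build_rate_table,
    diffusion_threshold,
    find_steady_segments,
    fit_decay,
    growth_velocity,
    mean_filament_length_ratio,
    mesh_size,
    monomer_consumption_fraction,
    per_filament_rate,
    per_network_rate,
)
from dendritic.errors import (
    DegenerateFitError,
    DomainError,
    InsufficientDataError,
    NormalizationError,
    TimeOrderingError,
)
from dendritic.flux import IntensityTrace, subtract_baseline


class TestSteadySegments:
    def test_exact_two_step_trace(self):
        """Two exact linear phases joined by a ramp: both recovered exactly."""
        t = np.arange(0.0, 400.0, 1.0)
        v1, v2 = 0.12, 0.05  # µm/s
        h = np.where(
            t < 180,
            v1 * t,
            np.where(t < 220, v1 * 180 + (v1 + v2) / 2 * (t - 180), 0.0),
        )
        h[t >= 220] = v1 * 180 + (v1 + v2) / 2 * 40 + v2 * (t[t >= 220] - 220)
        stress = np.where(t < 180, 100.0, np.where(t < 220, 300.0, 500.0))
        segs = find_steady_segments(AfmTrace(t, h, stress), min_duration=60.0)
        assert len(segs) >= 2
        slopes = sorted(s.velocity for s in segs)
        assert slopes[0] == pytest.approx(v2 * 60, rel=1e-9)
        assert slopes[-1] == pytest.approx(v1 * 60, rel=1e-9)

    def test_constant_height_single_segment(self):
        t = np.arange(0.0, 120.0, 1.0)
        segs = find_steady_segments(AfmTrace(t, np.zeros_like(t), np.full_like(t, 50.0)))
        assert len(segs) == 1
        assert segs[0].velocity == pytest.approx(0.0, abs=1e-12)

    def test_noisy_slope_within_two_percent(self, rng):
        v = 7.3 / 60.0  # µm/s
        t = np.arange(0.0, 600.0, 1.0)
        h = v * t + rng.normal(0.0, 0.010, t.size)  # 10 nm height noise
        segs = find_steady_segments(AfmTrace(t, h, np.zeros_like(t)))
        assert len(segs) == 1
        assert segs[0].velocity == pytest.approx(7.3, rel=0.02)

    def test_no_qualifying_window_is_empty(self):
        t = np.arange(0.0, 30.0, 1.0)  # shorter than min_duration
        segs = find_steady_segments(AfmTrace(t, t * 0.1, np.zeros_like(t)))
        assert segs == []


class TestGrowthVelocity:
    def test_slope_conversion(self):
        t = np.arange(0.0, 60.0, 1.0)
        assert growth_velocity(t, 0.1216666666 * t) == pytest.approx(7.3, rel=1e-6)

    def test_reversed_time_errors(self):
        t = np.arange(10.0, 0.0, -1.0)
        with pytest.raises(TimeOrderingError):
            growth_velocity(t, t)

    def test_insufficient_samples(self):
        with pytest.raises(InsufficientDataError):
            growth_velocity(np.array([0.0, 1.0]), np.array([0.0, 1.0]))

    def test_noisy_recovery(self, rng):
        t = np.arange(0.0, 60.0, 1.0)
        h = 0.1216 * t + rng.normal(0.0, 0.010, 60)
        assert growth_velocity(t, h) == pytest.approx(0.1216 * 60, rel=0.02)


class TestNormalizedRates:
    def test_product_identity(self):
        assert per_network_rate(2.0, 0.5, 1.0) == pytest.approx(1.0)

    def test_reference_maps_to_one(self):
        dens = np.array([1.0, 2.0, 3.0])
        vel = np.array([2.0, 1.0, 0.5])
        ref = dens[0] * vel[0]
        assert per_network_rate(dens, vel, ref)[0] == pytest.approx(1.0)

    def test_zero_reference_errors(self):
        with pytest.raises(NormalizationError):
            per_network_rate(np.ones(3), np.ones(3), 0.0)

    @pytest.mark.parametrize(
        "pnr,e_rel,expected", [(1.0, 1.0, 1.0), (0.5, 3.3, 0.5 / 3.3)]
    )
    def test_per_filament_quotient(self, pnr, e_rel, expected):
        assert per_filament_rate(pnr, e_rel) == pytest.approx(expected)

    def test_sixfold_drop(self):
        # per-network rate halves while E triples: per-filament falls 6-fold
        base = per_filament_rate(1.0, 1.0)
        assert per_filament_rate(0.5, 3.0) == pytest.approx(base / 6.0)

    def test_rate_table_reference_rows_are_one(self, gen_config):
        stress = [25.0, 510.0, 1020.0]
        tab = build_rate_table(
            stress,
            {"actin": np.array([1.0, 1.8, 2.2]), "CP": np.array([0.9, 1.6, 2.0])},
            np.array([7.2, 3.0, 1.2]),
            np.array([1.05, 2.4, 3.3]),
            reference_stress=25.0,
        )
        ref_rows = tab[tab.stress_pa == 25.0]
        assert np.allclose(ref_rows.per_network_rate, 1.0)
        assert np.allclose(ref_rows.per_filament_rate, 1.0)


class TestFluxBalance:
    @pytest.mark.parametrize(
        "r,k,cp,expected", [(1.0, 10.0, 0.1, 1.0), (10.0, 5.0, 0.1, 20.0)]
    )
    def test_rearrangement(self, r, k, cp, expected):
        assert barbed_end_density_steady_state(r, k, cp) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(
        r=st.floats(1e-3, 1e3), k=st.floats(1e-3, 1e2), cp=st.floats(1e-3, 10.0)
    )
    def test_balance_exact_round_trip(self, r, k, cp):
        e = barbed_end_density_steady_state(r, k, cp)
        assert k * cp * e == pytest.approx(r, rel=1e-12)

    def test_inverse_proportionality(self):
        e1 = barbed_end_density_steady_state(10.0, 4.0, 0.2)
        e2 = barbed_end_density_steady_state(10.0, 2.0, 0.2)
        assert e2 == pytest.approx(2.0 * e1)


class TestFitDecay:
    def test_single_exponential_exact(self):
        x = np.array([0.0, 100.0, 250.0, 500.0, 800.0, 1200.0])
        y = np.exp(-x / 300.0)
        fit = fit_decay(x, y, n_components=1)
        assert fit.decay_constants[0] == pytest.approx(300.0, rel=1e-6)

    def test_double_exponential_ordered_recovery(self):
        x = np.linspace(0.0, 1500.0, 25)
        y = 0.5 * np.exp(-x / 50.0) + 0.5 * np.exp(-x / 500.0)
        fit = fit_decay(x, y, n_components=2)
        assert fit.decay_constants[0] == pytest.approx(50.0, rel=0.01)
        assert fit.decay_constants[1] == pytest.approx(500.0, rel=0.01)
        assert fit.amplitudes[0] == pytest.approx(0.5, rel=0.01)

    def test_constant_response_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_decay(np.arange(6.0), np.ones(6), n_components=1)

    def test_rescaling_invariance(self):
        x = np.linspace(0.0, 900.0, 12)
        y = np.exp(-x / 250.0)
        tau1 = fit_decay(x, y, 1).decay_constants[0]
        tau2 = fit_decay(x, 37.0 * y, 1).decay_constants[0]
        assert tau2 == pytest.approx(tau1, rel=1e-9)


class TestAncillary:
    def test_consumption_worked_example(self):
        # 150 µM polymer in <0.01 µl of 5 µM in 150 µl: 0.2%, below the 0.3% bound
        frac = monomer_consumption_fraction(150.0, 0.01, 5.0, 150.0)
        assert frac == pytest.approx(0.002, rel=1e-12)
        assert frac <= 0.003

    def test_consumption_linearity(self):
        assert monomer_consumption_fraction(300.0, 0.01, 5.0, 150.0) == pytest.approx(0.004)

    def test_mesh_size_unit_root(self):
        assert mesh_size(1.47**2) == pytest.approx(1.0)

    def test_mesh_size_formula(self):
        # literal 1.47/sqrt(C_A) at the densest networks (~1250 µM)
        assert mesh_size(1250.0) == pytest.approx(1.47 / np.sqrt(1250.0), rel=1e-12)

    def test_mesh_scaling(self):
        assert mesh_size(400.0) == pytest.approx(2.0 * mesh_size(1600.0))

    def test_diffusion_threshold(self):
        assert diffusion_threshold(0.045) == pytest.approx(0.018)

    def test_length_ratio_scale_invariance(self):
        a = np.array([1.0, 2.0, 3.0])
        cp = np.array([0.2, 0.4, 0.6])
        r1 = mean_filament_length_ratio(a, cp)
        r2 = mean_filament_length_ratio(2 * a, 2 * cp)
        assert np.allclose(r1, r2)
        assert np.allclose(r1, r1[0])  # proportional channels: flat ratio

    def test_baseline_subtraction(self):
        t = np.arange(0.0, 100.0, 1.0)
        d = np.where(t < 20, 0.3, 1.3)  # NPF-bound lag signal 0.3
        out = subtract_baseline(IntensityTrace(t, "actin", d), (0.0, 19.0))
        assert out.density[-1] == pytest.approx(1.0)
        assert out.density[0] == pytest.approx(0.0)
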