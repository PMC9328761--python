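"""Stochastic network-growth simulator vs mean-field and exact oracles."""

import dataclasses
import warnings

import numpy as np
import pytest

from dendritic import RatchetParams
from dendritic.errors import InsufficientDataError, StationarityWarning
from dendritic.simulate import (
    SimParams,
    load_series_experiment,
    mean_field_barbed_end_density,
    simulate,
    steady_state_summary,
)


class TestEventBookkeeping:
    def test_no_capping_means_growing_end_count(self, small_sim):
        p = small_sim(k_cap0=0.0, seed=1)
        traj = simulate(p, duration=20.0)
        assert np.all(np.diff(traj.free_ends) >= 0)
        assert traj.capped_lengths.size == 0

    def test_subunit_conservation(self, small_sim):
        """Polymer mass equals nucleation + elongation events exactly."""
        traj = simulate(small_sim(seed=2), duration=30.0)
        assert traj.polymer_subunits[-1] == (
            traj.nucleation_events[-1] + traj.elongation_events[-1]
        )

    def test_height_non_decreasing(self, small_sim):
        traj = simulate(small_sim(seed=3), duration=30.0)
        assert np.all(np.diff(traj.height) >= 0)

    def test_seed_reproducibility(self, small_sim):
        t1 = simulate(small_sim(seed=7), duration=10.0)
        t2 = simulate(small_sim(seed=7), duration=10.0)
        assert np.array_equal(t1.free_ends, t2.free_ends)
        assert np.array_equal(t1.height, t2.height)


class TestGeometricLengthOracle:
    def test_mean_capped_length_without_nucleation(self, small_sim):
        """With nucleation off, a filament caps after a geometric number of
        elongation steps: mean length 1 + k_on/k_cap (gap factors cancel for
        equal gap sizes)."""
        p = small_sim(k_nuc_max=0.0, k_on0=20.0, k_cap0=0.5, seed=4)
        traj = simulate(p, duration=40.0, initial_filaments=2000)
        lens = traj.capped_lengths
        assert lens.size > 1500
        expected = 1.0 + 20.0 / 0.5
        se = lens.std(ddof=1) / np.sqrt(lens.size)
        assert abs(lens.mean() - expected) < 3.0 * se


class TestMeanFieldFixedPoint:
    def test_zero_stress_fixed_point(self, small_sim):
        p = small_sim(seed=5)
        traj = simulate(p, duration=150.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", StationarityWarning)
            s = steady_state_summary(traj, (50.0, 150.0))
        e_star = mean_field_barbed_end_density(p)
        assert abs(s.mean_free_end_density - e_star) < 3.0 * s.se_free_end_density

    def test_fixed_point_grid(self, small_sim):
        """Simulated stationary E matches the deterministic fixed point
        within 3 SE for >= 95% of a 12-point parameter grid."""
        grid = []
        for k_cap0 in (0.3, 0.48, 0.8):
            for k_nuc in (0.02, 0.037):
                for k_be in (2.5e-4, 5e-4):
                    grid.append(dict(k_cap0=k_cap0, k_nuc_max=k_nuc, K_be=k_be))
        hits = 0
        for i, over in enumerate(grid):
            p = small_sim(seed=100 + i, **over)
            traj = simulate(p, duration=150.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", StationarityWarning)
                s = steady_state_summary(traj, (50.0, 150.0))
            e_star = mean_field_barbed_end_density(p)
            hits += abs(s.mean_free_end_density - e_star) < 3.0 * s.se_free_end_density
        assert hits >= int(np.ceil(0.95 * len(grid))) - 1

    def test_flux_balance_at_stationarity(self, small_sim):
        traj = simulate(small_sim(seed=6), duration=150.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", StationarityWarning)
            s = steady_state_summary(traj, (50.0, 150.0))
        se = np.hypot(s.se_nucleation_flux, s.se_capping_flux)
        assert abs(s.capping_flux - s.nucleation_flux) < 3.0 * se

    def test_stoichiometry_cp_to_arp(self, small_sim):
        """Every capped filament carries one cap and one nucleus, so the
        network CP:Arp2/3 event ratio approaches 1."""
        traj = simulate(small_sim(seed=8), duration=150.0)
        ratio = traj.capping_events[-1] / traj.nucleation_events[-1]
        assert 0.9 < ratio <= 1.0


class TestSummaryWindows:
    def test_window_before_events_errors(self, small_sim):
        traj = simulate(small_sim(seed=9), duration=30.0)
        with pytest.raises(InsufficientDataError):
            steady_state_summary(traj, (0.0, 0.4))

    def test_disjoint_windows_agree(self, small_sim):
        traj = simulate(small_sim(seed=10), duration=260.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", StationarityWarning)
            s1 = steady_state_summary(traj, (60.0, 160.0))
            s2 = steady_state_summary(traj, (160.0, 260.0))
        se = np.hypot(s1.se_free_end_density, s2.se_free_end_density)
        assert abs(s1.mean_free_end_density - s2.mean_free_end_density) < 3.0 * se


class TestLoadSeries:
    STRESSES = (0.0, 250.0, 600.0, 1000.0)

    def _series(self, small_sim, **ratchet_over):
        p = small_sim(seed=11, ratchet=RatchetParams(**ratchet_over))
        return load_series_experiment(p, self.STRESSES, hold=90.0, burn_in=40.0)

    def test_monotone_adaptation(self, small_sim):
        """Velocity falls and free-end density rises along the stress ladder."""
        summaries = self._series(small_sim)
        e = [s.mean_free_end_density for s in summaries]
        v = [s.velocity for s in summaries]
        assert e[-1] > e[0]
        assert v[-1] < v[0]
        # monotone within combined SE
        for a, b in zip(summaries, summaries[1:]):
            tol = 3.0 * np.hypot(a.se_free_end_density, b.se_free_end_density)
            assert b.mean_free_end_density > a.mean_free_end_density - tol

    def test_matched_gaps_load_invariant_length(self, small_sim):
        """Equal gap sizes for monomer and CP keep filament length
        load-invariant: the length-vs-stress slope CI contains 0."""
        summaries = self._series(small_sim)  # δ_cap = δ_actin = 2.7 nm
        slope, se = _length_slope(summaries)
        assert abs(slope) < 2.0 * se

    def test_bulky_gap_lengthens_filaments_under_load(self, small_sim):
        """A larger capping gap slows capping more than elongation under
        load, so filaments lengthen with stress."""
        summaries = self._series(small_sim, delta_cap_wt=5.4, delta_cap_bulky=5.4)
        lengths = [s.mean_capped_length for s in summaries]
        assert lengths[-1] > lengths[0]
        slope, se = _length_slope(summaries)
        assert slope > 2.0 * se

    def test_seed_independence_of_the_law(self, small_sim):
        p1 = small_sim(seed=21)
        p2 = small_sim(seed=22)
        s1 = load_series_experiment(p1, (300.0,), hold=120.0, burn_in=40.0)[0]
        s2 = load_series_experiment(p2, (300.0,), hold=120.0, burn_in=40.0)[0]
        se = np.hypot(s1.se_free_end_density, s2.se_free_end_density)
        assert abs(s1.mean_free_end_density - s2.mean_free_end_density) < 3.0 * se


def _length_slope(summaries):
    from scipy import stats

    x = np.array([s.stress for s in summaries])
    y = np.array([s.mean_capped_length for s in summaries])
    w = np.array([s.se_capped_length for s in summaries])
    lr = stats.linregress(x, y)
    return lr.slope, lr.stderr


class TestParamsValidation:
    def test_schedule_must_increase(self):
        with pytest.raises(Exception):
            SimParams(stress_schedule=((10.0, 0.0), (5.0, 100.0)))

    def test_paused_episode_logged(self):
        # nonzero stress with no filaments: load coupling pauses, run continues
        p = SimParams(area=0.5, k_on0=5.0, k_nuc_max=1e-4, k_cap0=0.0,
                      stress_schedule=((0.0, 500.0),), seed=12)
        traj = simulate(p, duration=5.0)
        assert traj.paused_episodes >= 1
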