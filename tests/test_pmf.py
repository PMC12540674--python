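"""Guiding potential, Jarzynski averaging, ASMD stitching and WHAM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from confswitch.constants import KB_KCAL, beta as beta_of
from confswitch.errors import ParameterError
from confswitch.pmf import (
    PullingSpec,
    SegmentWork,
    UmbrellaWindow,
    WorkEnsemble,
    asmd_stitch,
    guiding_energy_force,
    jarzynski_segment,
    wham_1d,
)
from confswitch.synthetic import LangevinWorkSpec, gen_umbrella_samples, gen_work_ensemble

BETA300 = beta_of(300.0)


class TestGuidingPotential:
    def spec(self, k=2.5, v=1.0):
        return PullingSpec(k=k, v=v, n=np.array([0.0, 0.0, 1.0]), X0=np.zeros(3))

    def test_on_schedule_zero(self):
        spec = self.spec()
        U, F = guiding_energy_force(spec, t=2.0, X_t=np.array([0.0, 0.0, 2.0]))
        assert U == pytest.approx(0.0)
        np.testing.assert_allclose(F, 0.0)

    def test_hand_value_at_unit_lag(self):
        # k = 2.5 kcal/mol/A^2 (the standard pulling spring), lag = 1 A
        spec = self.spec()
        U, F = guiding_energy_force(spec, t=1.0, X_t=np.zeros(3))
        assert U == pytest.approx(1.25)
        assert np.linalg.norm(F) == pytest.approx(2.5)
        # force points along the pulling direction, toward the schedule point
        assert F[2] > 0

    def test_homogeneity_in_k(self):
        U1, F1 = guiding_energy_force(self.spec(k=2.5), 1.0, np.zeros(3))
        U2, F2 = guiding_energy_force(self.spec(k=5.0), 1.0, np.zeros(3))
        assert U2 == pytest.approx(2 * U1)
        np.testing.assert_allclose(F2, 2 * F1)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ParameterError):
            PullingSpec(k=1.0, v=1.0, n=np.array([0.0, 0.0, 2.0]), X0=np.zeros(3))

    def test_negative_time_rejected(self):
        with pytest.raises(ParameterError):
            guiding_energy_force(self.spec(), -1.0, np.zeros(3))


class TestJarzynski:
    def test_constant_work(self):
        assert jarzynski_segment(np.full(10, 3.7), BETA300) == pytest.approx(3.7)

    def test_two_value_hand_case(self):
        # beta = 1, works {0, ln 2}: -ln((1 + 1/2)/2) = ln(4/3)
        got = jarzynski_segment(np.array([0.0, np.log(2.0)]), 1.0)
        assert got == pytest.approx(0.28768, abs=1e-5)

    def test_gaussian_work_closed_form(self):
        rng = np.random.default_rng(42)
        mu, sigma = 5.0, 1.0
        works = rng.normal(mu, sigma, size=10_000)
        expected = mu - BETA300 * sigma**2 / 2
        assert expected == pytest.approx(4.161, abs=2e-3)
        assert jarzynski_segment(works, BETA300) == pytest.approx(expected, abs=0.1)

    def test_no_underflow_at_large_beta_work(self):
        works = np.full(5, 1e4)
        assert jarzynski_segment(works, BETA300) == pytest.approx(1e4)

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=30),
        st.floats(0.1, 5.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_jensen_bound_and_permutation_invariance(self, works, beta):
        w = np.array(works)
        est = jarzynski_segment(w, beta)
        assert est <= w.mean() + 1e-9
        if np.ptp(w) > 1e-6:
            assert est < w.mean()
        perm = jarzynski_segment(w[::-1].copy(), beta)
        assert perm == pytest.approx(est, abs=1e-9)

    def test_continuity_in_beta(self):
        w = np.array([0.0, 1.0, 2.0])
        vals = [jarzynski_segment(w, b) for b in (1.0, 1.0001)]
        assert abs(vals[1] - vals[0]) < 1e-3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            jarzynski_segment(np.array([]), 1.0)


class TestASMDStitch:
    def test_single_segment_single_trajectory(self):
        xi = np.linspace(0.0, 1.0, 5)
        w = np.array([[0.0, 0.5, 1.2, 1.8, 2.0]])
        profile = asmd_stitch(WorkEnsemble([SegmentWork(xi, w)], beta=BETA300))
        np.testing.assert_allclose(profile.dG, w[0])
        assert profile.seed_indices == [0]

    def test_two_deterministic_segments_additive(self):
        xi1, xi2 = np.linspace(0, 1, 3), np.linspace(1, 2, 3)
        seg1 = SegmentWork(xi1, np.array([[0.0, 1.0, 2.0]]))
        seg2 = SegmentWork(xi2, np.array([[0.0, 2.0, 3.0]]))
        profile = asmd_stitch(WorkEnsemble([seg1, seg2], beta=BETA300))
        assert profile.dG[-1] == pytest.approx(5.0)
        np.testing.assert_allclose(profile.segment_dG, [2.0, 3.0])
        # continuity at the boundary
        assert profile.dG[2] == pytest.approx(2.0)

    def test_planted_five_segment_recovery(self):
        targets = np.array([1.0, 2.0, 0.0, -1.0, 3.0])
        sigma, tracks = 0.5, 25
        spec = LangevinWorkSpec(dG_targets=targets, sigma=sigma, trajectories=tracks, seed=3)
        profile = asmd_stitch(gen_work_ensemble(spec, BETA300))
        # per-segment: 3 standard errors of the 25-track work mean
        np.testing.assert_allclose(profile.segment_dG, targets, atol=3 * sigma / np.sqrt(tracks))
        assert profile.dG[-1] == pytest.approx(targets.sum(), abs=0.3)

    def test_total_equals_segment_sum(self, rng):
        spec = LangevinWorkSpec(dG_targets=rng.normal(size=4), sigma=1.0, trajectories=10, seed=9)
        profile = asmd_stitch(gen_work_ensemble(spec, BETA300))
        assert profile.dG[-1] == pytest.approx(profile.segment_dG.sum(), abs=1e-9)

    def test_seed_closest_to_average(self):
        xi = np.linspace(0, 1, 3)
        w = np.array([[0.0, 0.1, 0.2], [0.0, 1.0, 2.0], [0.0, 0.2, 0.35]])
        e = WorkEnsemble([SegmentWork(xi, w)], beta=1.0)
        profile = asmd_stitch(e)
        dG = jarzynski_segment(w[:, -1], 1.0)
        expect = int(np.argmin(np.abs(w[:, -1] - dG)))
        assert profile.seed_indices == [expect]

    def test_discontinuous_boundaries_rejected(self):
        seg1 = SegmentWork(np.linspace(0, 1, 3), np.zeros((1, 3)))
        seg2 = SegmentWork(np.linspace(2, 3, 3), np.zeros((1, 3)))
        with pytest.raises(ValueError):
            WorkEnsemble([seg1, seg2], beta=1.0)


def flat_potential(x):
    return 0.0


def double_well(x, barrier=3.0, half_width=2.0):
    return barrier * ((x / half_width) ** 2 - 1.0) ** 2


class TestWHAM:
    def test_single_unbiased_window_closed_form(self):
        edges = np.linspace(0, 4, 5)
        counts = np.array([40.0, 20.0, 10.0, 30.0])
        w = UmbrellaWindow(centre=2.0, spring=0.0, bin_edges=edges, counts=counts)
        profile = wham_1d([w], temperature=300.0)
        expected = -KB_KCAL * 300.0 * np.log(counts / counts.sum())
        expected -= expected.min()
        np.testing.assert_allclose(profile.dG, expected, atol=1e-6)

    def test_flat_potential_recovers_flat_pmf(self):
        windows = gen_umbrella_samples(
            flat_potential, np.linspace(-3, 3, 13), spring=10.0,
            n_per_window=50_000, temperature=300.0, seed=5,
        )
        profile = wham_1d(windows, 300.0)
        # ignore sparse edge bins beyond the outermost centres
        core = (profile.xi > -3) & (profile.xi < 3)
        assert profile.dG[core].max() - profile.dG[core].min() <= 0.1

    def test_double_well_barrier_recovery(self):
        windows = gen_umbrella_samples(
            double_well, np.linspace(-3.2, 3.2, 12), spring=10.0,
            n_per_window=5000, temperature=300.0, seed=6,
        )
        profile = wham_1d(windows, 300.0)
        barrier = profile.dG[np.abs(profile.xi) < 0.5].max() - profile.dG.min()
        assert barrier == pytest.approx(3.0, abs=0.3)

    def test_agrees_with_asmd_on_double_well(self):
        # equilibrium (WHAM) and nonequilibrium (segmented Jarzynski) routes
        # should agree on the planted free-energy difference
        xi_pts = np.linspace(-2.0, 0.0, 6)  # well bottom -> barrier top
        d_targets = np.diff([double_well(x) for x in xi_pts])
        spec = LangevinWorkSpec(
            dG_targets=d_targets, sigma=0.3, trajectories=50,
            boundaries=xi_pts, seed=8,
        )
        asmd_profile = asmd_stitch(gen_work_ensemble(spec, BETA300))
        windows = gen_umbrella_samples(
            double_well, np.linspace(-3.2, 3.2, 14), spring=12.0,
            n_per_window=5000, temperature=300.0, seed=9,
        )
        wham_profile = wham_1d(windows, 300.0)
        wham_rise = wham_profile.dG[np.abs(wham_profile.xi) < 0.3].max() - wham_profile.dG.min()
        assert asmd_profile.dG[-1] - asmd_profile.dG.min() == pytest.approx(wham_rise, abs=0.3)

    def test_non_overlapping_windows_warn(self):
        edges = np.linspace(0, 10, 21)
        c1 = np.zeros(20); c1[0] = 5
        c2 = np.zeros(20); c2[-1] = 5
        w1 = UmbrellaWindow(0.25, 50.0, edges, c1)
        w2 = UmbrellaWindow(9.75, 50.0, edges, c2)
        with pytest.warns(UserWarning):
            wham_1d([w1, w2], 300.0)
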