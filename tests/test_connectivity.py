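"""Gaussian-copula MI, lagged profiles, boundary maps, cluster permutation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from storyrecall.connectivity import (boundary_map, cluster_perm_maps,
                                      conditional_copula_mi, copula_mi,
                                      lagged_profile, peak_locked_mi)
from storyrecall.preprocess import clean_and_align
from storyrecall.synth import SimulationTruth, gen_two_run_recording


class TestCopulaMI:
    def test_independent_gaussians_near_zero(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            vals.append(copula_mi(rng.standard_normal((1, 1000)),
                                  rng.standard_normal((1, 1000))))
        assert abs(np.mean(vals)) < 0.01

    def test_bivariate_gaussian_closed_form(self):
        rng = np.random.default_rng(1)
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        xy = rng.multivariate_normal([0, 0], cov, size=1000).T
        expected = -0.5 * np.log(1 - 0.8**2)
        assert copula_mi(xy[:1], xy[1:]) == pytest.approx(expected, rel=0.05)

    def test_monotone_transform_invariance_exact(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((1, 400))
        y = 0.7 * x + 0.5 * rng.standard_normal((1, 400))
        assert copula_mi(x, y) == pytest.approx(copula_mi(x, y**3), abs=1e-12)

    def test_bias_corrected_lower_bound_on_null(self):
        worst = min(
            copula_mi(np.random.default_rng(s).standard_normal((2, 200)),
                      np.random.default_rng(1000 + s).standard_normal((2, 200)))
            for s in range(20)
        )
        assert worst >= -0.02

    def test_constant_dimension_named(self):
        x = np.vstack([np.ones(100), np.arange(100.0)])
        with pytest.raises(ValueError, match="dimension 0"):
            copula_mi(x, np.random.default_rng(0).standard_normal((1, 100)))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="50"):
            copula_mi(np.arange(20.0), np.arange(20.0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((1, 300))
        y = 0.5 * x + rng.standard_normal((1, 300))
        assert copula_mi(x, y) == pytest.approx(copula_mi(y, x), abs=1e-10)


class TestConditionalCopulaMI:
    def test_irrelevant_conditioner_preserves_mi(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((1, 2000))
        y = 0.8 * x + 0.6 * rng.standard_normal((1, 2000))
        z = rng.standard_normal((1, 2000))
        assert conditional_copula_mi(x, y, z) == pytest.approx(copula_mi(x, y),
                                                               abs=0.02)

    def test_markov_chain_conditioning_removes_dependence(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(3000)
        z = x + 0.5 * rng.standard_normal(3000)
        y = z + 0.5 * rng.standard_normal(3000)
        assert copula_mi(x, y) > 0.2
        assert abs(conditional_copula_mi(x, y, z)) < 0.02

    def test_conditioner_equal_to_target_kills_mi(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(1000)
        y = 0.9 * x + 0.3 * rng.standard_normal(1000)
        assert abs(conditional_copula_mi(x, y, y)) < 0.02


class TestLaggedProfile:
    def test_identity_placement_maximal_at_zero_lag(self):
        rng = np.random.default_rng(6)
        cpr = rng.standard_normal((4, 4000))
        target = cpr.mean(axis=0, keepdims=True)
        prof = lagged_profile(cpr, target, [(500, 3500)],
                              np.arange(-30, 31, 5), condition_zero_lag=False)
        assert np.argmax(prof) == np.flatnonzero(np.arange(-30, 31, 5) == 0)[0]

    def test_independent_noise_flat_profile(self):
        rng = np.random.default_rng(7)
        prof = lagged_profile(rng.standard_normal((4, 4000)),
                              rng.standard_normal((2, 4000)),
                              [(500, 3500)], np.arange(-30, 31, 10))
        assert prof.max() < 0.02

    def test_out_of_span_window_dropped_with_warning(self):
        rng = np.random.default_rng(8)
        with pytest.warns(UserWarning, match="dropped"):
            prof = lagged_profile(rng.standard_normal((2, 1000)),
                                  rng.standard_normal((1, 1000)),
                                  [(100, 900), (950, 1200)], np.array([0, 5]))
        assert prof.size == 2

    def test_planted_coupling_lag_recovered(self, planted_recording):
        rec = planted_recording
        fs = rec["run1"].fs
        wins = [((p - 500) * fs / 1000, (p + 500) * fs / 1000)
                for p in rec["event_ms"]]
        lag_grid = np.arange(-80, -60, 1)  # 10 ms steps around the planted lead
        full_grid = np.arange(-100, 101, 4)
        hippo = rec["run2"].data[16:17]
        prof = lagged_profile(rec["run2"].data[:4], hippo, wins, full_grid)
        best = full_grid[np.argmax(prof)]
        assert abs(best * 1000 / fs - (-700.0)) <= 40  # coarse grid
        fine = lagged_profile(rec["run2"].data[:4], hippo, wins, lag_grid)
        assert abs(lag_grid[np.argmax(fine)] * 1000 / fs - (-700.0)) <= 20


class TestBoundaryMap:
    def test_planted_geometry_recovered_within_one_grid_step(self):
        # coupling 730 ms before boundaries, hippocampus lagging by 270 ms
        fs = 100.0
        bounds = np.arange(8000.0, 112000.0, 8000.0)
        wins = [(b - 730 - 500, b - 730 + 500) for b in bounds]
        truth = SimulationTruth(np.zeros(8), np.array([], dtype=int), bounds,
                                270.0, wins, seed=21, coupling_strength=1.5)
        r1, r2, env, _ = gen_two_run_recording(8, 1, 120.0, truth, snr=1.0)
        r1, r2, env = clean_and_align(r1, r2, env)
        lag_grid = np.arange(-60, 61, 5)  # 50 ms steps
        dist_grid = np.arange(-300, 101, 10)  # 100 ms steps
        m = boundary_map(r1.data[:8], r1.data[8:9],
                         (bounds * fs / 1000).astype(int), fs, dist_grid, lag_grid)
        i, j = np.unravel_index(np.argmax(m.mi), m.mi.shape)
        assert abs(lag_grid[i] * 10 - 270) <= 50
        assert abs(dist_grid[j] * 10 - (-730)) <= 100

    def test_shape_matches_grids(self, planted_recording):
        rec = planted_recording
        lag_grid = np.arange(-20, 21, 10)
        dist_grid = np.arange(-100, 1, 50)
        m = boundary_map(rec["run1"].data[:3], rec["run1"].data[16:17],
                         np.array([3000, 6000, 9000]), 100.0, dist_grid, lag_grid)
        assert m.mi.shape == (lag_grid.size, dist_grid.size)


class TestClusterPerm:
    def test_identical_maps_no_clusters_p_one(self):
        base = np.random.default_rng(9).standard_normal((10, 8))
        a = np.stack([base] * 3)
        b = np.stack([base] * 3)
        out = cluster_perm_maps(a, b, n_perm=100, seed=0)
        assert len(out.clusters) == 0
        assert out.p_perm == 1.0

    def test_planted_roi_cluster_detected(self):
        detected = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal((6, 12, 10))
            b = rng.standard_normal((8, 12, 10))
            a[:, 4:7, 3:6] += 2.0  # ROI-only block of extra MI
            out = cluster_perm_maps(a, b, n_perm=200, seed=seed)
            detected += out.p_perm < 0.05
        assert detected >= 9

    def test_plausible_window_restricts_clusters(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal((4, 10, 8))
        a[:, 0, 0] += 5.0  # effect outside the plausible window
        b = rng.standard_normal((4, 10, 8))
        mask = np.zeros((10, 8), dtype=bool)
        mask[5:, 4:] = True
        out = cluster_perm_maps(a, b, n_perm=100, seed=0, plausible_mask=mask)
        for c in out.clusters:
            assert not c["mask"][0, 0]

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            cluster_perm_maps(np.zeros((3, 5, 5)), np.zeros((3, 6, 5)))

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            cluster_perm_maps(np.zeros((1, 5, 5)), np.zeros((3, 5, 5)))


class TestPeakLockedMI:
    def test_run2_specific_coupling_found_only_in_run2(self):
        fs = 100.0
        peaks_ms = np.arange(10000.0, 110000.0, 8000.0)
        wins = [(p - 500.0, p + 500.0) for p in peaks_ms]
        truth = SimulationTruth(np.zeros(12), np.array([], dtype=int), [1000.0],
                                -700.0, wins, seed=31, coupling_runs=(2,),
                                coupling_strength=1.5)
        r1, r2, env, _ = gen_two_run_recording(12, 3, 120.0, truth, snr=1.0)
        r1, r2, env = clean_and_align(r1, r2, env)
        n = r1.n_samples
        tt = np.arange(n) / fs * 1000.0
        tc = sum(np.exp(-0.5 * ((tt - p) / 400.0) ** 2) for p in peaks_ms)
        tc = tc + 0.05 * np.random.default_rng(0).standard_normal(n)
        lag_grid = np.arange(-90, -49, 2)  # 20 ms steps spanning the planted lead
        res = peak_locked_mi(
            {1: r1.data[:6], 2: r2.data[:6]},
            {1: [r1.data[12 + i : 13 + i] for i in range(3)],
             2: [r2.data[12 + i : 13 + i] for i in range(3)]},
            {1: [r1.data[6 + i : 7 + i] for i in range(3)],
             2: [r2.data[6 + i : 7 + i] for i in range(3)]},
            tc, fs, 0, lag_grid, fs, n_perm=30, seed=0,
        )
        best2 = lag_grid[np.argmax(res["run2"]["mean"])] * 10
        assert abs(best2 - (-700)) <= 40
        assert res["run2"]["conjunction"].any()
        assert res["run2"]["mean"].max() > 5 * max(res["run1"]["mean"].max(), 1e-3)

    def test_too_few_peaks_rejected(self):
        rng = np.random.default_rng(11)
        flat = rng.standard_normal(3000) * 0 + np.linspace(0, 1, 3000)
        with pytest.raises(ValueError, match="peaks"):
            peak_locked_mi({1: rng.standard_normal((2, 3000))},
                           {1: [rng.standard_normal((1, 3000))]},
                           {1: [rng.standard_normal((1, 3000))]},
                           flat, 100.0, 0, np.array([0]), 100.0)
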