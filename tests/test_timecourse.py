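"""Projected partial predictions, recall time-course, peaks, locked analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from storyrecall.behavior import make_word_table
from storyrecall.granger import cross_run_gc, gc_pair
from storyrecall.preprocess import AudioEnvelope, RecordingRun
from storyrecall.synth import SimulationTruth, gen_two_run_recording
from storyrecall.timecourse import (boundary_locked, detect_peaks,
                                    partial_prediction, projection,
                                    recall_timecourse, word_correlation)


class TestPartialPrediction:
    def test_zero_coefficients_zero_series(self):
        assert not partial_prediction(np.zeros(3), np.arange(10.0)).any()

    def test_hand_computation_order_one(self):
        out = partial_prediction(np.array([2.0]), np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [2.0, 4.0])

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            partial_prediction(np.ones(5), np.ones(5))

    def test_recovers_planted_cross_component(self):
        rng = np.random.default_rng(0)
        n = 8000
        y = rng.standard_normal(n)
        x = np.zeros(n)
        x[2:] = 0.9 * y[:-2]
        x += 0.05 * rng.standard_normal(n)
        r = gc_pair(x, y, rng.standard_normal(n), p=4)
        pred = partial_prediction(r.model_x.a_cross, y - y.mean())
        planted = x[4:] - x.mean()
        assert np.corrcoef(pred, planted)[0, 1] > 0.9


class TestProjection:
    def test_ones_give_one(self):
        assert np.all(projection(np.ones((3, 5)), np.ones((3, 5))) == 1.0)

    def test_antiparallel_nonpositive(self):
        d = np.random.default_rng(1).standard_normal((3, 100))
        np.testing.assert_allclose(projection(-d, d), -(d**2).mean(axis=0))

    def test_orthogonal_time_average_near_zero(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((4, 5000))
        b = rng.standard_normal((4, 5000))
        assert abs(projection(a, b).mean()) < 0.02

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            projection(np.ones((2, 5)), np.ones((3, 5)))


class TestRecallTimecourse:
    def test_identical_runs_cancel_exactly(self, planted_recording):
        rec = planted_recording
        run1 = rec["run1"]
        run_same = RecordingRun(run1.data.copy(), run1.fs,
                                list(run1.channel_labels), 2)
        _, results = cross_run_gc(run1, run_same, rec["env"], order=5,
                                  channels=list(range(4)))
        tc = recall_timecourse(run1, run_same, results, np.arange(4))
        np.testing.assert_allclose(tc.values, 0.0, atol=1e-12)

    def test_matches_independent_direct_implementation(self, planted_recording, gc_fit):
        """Oracle: convolution-based partial forecast + explicit projection
        difference + cumulative-sum moving average, coded independently."""
        rec = planted_recording
        run1, run2 = rec["run1"], rec["run2"]
        results = gc_fit["results"]
        channels = np.arange(4)
        tc = recall_timecourse(run1, run2, results, channels)
        p = max(results[c].order for c in channels)
        comps = []
        for c in channels:
            r = results[c]
            x = run1.data[c] - run1.data[c].mean()
            y = run2.data[c] - run2.data[c].mean()
            fwd = np.convolve(y, np.concatenate([[0.0], r.model_x.a_cross]))[: x.size]
            rev = np.convolve(x, np.concatenate([[0.0], r.model_y.a_cross]))[: x.size]
            comps.append((fwd * x - rev * y)[p:])
        raw = np.mean(comps, axis=0)
        w = int(run1.fs)
        padded = np.concatenate([np.zeros(w), raw, np.zeros(w)])
        csum = np.cumsum(padded)
        half_lo, half_hi = w // 2, w - w // 2
        direct = np.empty(raw.size)
        for t in range(raw.size):
            lo = max(t - half_lo, 0)
            hi = min(t + half_hi, raw.size)
            direct[t] = raw[lo:hi].mean()
        np.testing.assert_allclose(tc.values, direct, atol=1e-8)
        np.testing.assert_allclose(tc.per_channel, comps, atol=1e-8)

    def test_windowed_anticipation_localized(self):
        # anticipation confined to windows: the time-course is higher inside
        rng = np.random.default_rng(3)
        from scipy import signal as sig

        n = 24000
        sos = sig.butter(4, 8.0, fs=100.0, output="sos")
        lat = sig.sosfiltfilt(sos, rng.standard_normal(n + 40))
        lat /= lat.std()
        shift = 20
        win = np.zeros(n, dtype=bool)
        starts = np.arange(2000, 22000, 4000)
        for s in starts:
            win[s : s + 1000] = True
        x = lat[:n] + 0.7 * rng.standard_normal(n)
        y = np.where(win, lat[shift : n + shift], lat[:n]) + 0.7 * rng.standard_normal(n)
        env = np.abs(lat[:n]) + 0.1
        r1 = RecordingRun(x[None, :], 100.0, ["c"], 1)
        r2 = RecordingRun(y[None, :], 100.0, ["c"], 2)
        _, results = cross_run_gc(r1, r2, AudioEnvelope(env, 100.0), order=25)
        tc = recall_timecourse(r1, r2, results, np.array([0]))
        mask = win[tc.start_sample :]
        assert tc.values[mask].mean() > tc.values[~mask].mean()

    def test_needs_at_least_one_channel(self, planted_recording, gc_fit):
        with pytest.raises(ValueError):
            recall_timecourse(planted_recording["run1"], planted_recording["run2"],
                              gc_fit["results"], np.array([], dtype=int))


class TestProjectionTracksDeltaF:
    def test_rank_correlation_across_snr_levels(self):
        """The time-mean of the unsmoothed projection difference orders
        channels the same way ΔF does across planted effect strengths."""
        snrs = [0.0, 0.3, 0.6, 1.0, 1.5, 2.5]
        mean_proj, delta_f = [], []
        for i, snr in enumerate(snrs):
            shifts = np.array([200.0])
            truth = SimulationTruth(shifts, np.array([0]), [1000.0], 0.0, [],
                                    seed=50 + i)
            r1, r2, env, _ = gen_two_run_recording(1, 0, 90.0, truth,
                                                   snr=max(snr, 1e-6))
            _, results = cross_run_gc(r1, r2, env, order=22)
            tc = recall_timecourse(r1, r2, results, np.array([0]))
            mean_proj.append(tc.per_channel.mean())
            delta_f.append(results[0].delta_f)
        rho = sps.spearmanr(mean_proj, delta_f).statistic
        assert rho > 0.9


class TestDetectPeaks:
    def _bumpy(self, n=6000, centers=(1000, 3000, 5000), heights=(1.0, 2.0, 1.5)):
        t = np.arange(n, dtype=float)
        return sum(h * np.exp(-0.5 * ((t - c) / 60.0) ** 2)
                   for c, h in zip(centers, heights))

    def test_three_bumps_three_peaks_at_maxima(self):
        tc = self._bumpy()
        peaks = detect_peaks(tc, fs=100.0, percentile=80)
        assert peaks.times.size == 3
        assert np.all(np.abs(peaks.times - np.array([1000, 3000, 5000])) < 30)

    def test_monotone_ramp_single_peak_in_tail(self):
        peaks = detect_peaks(np.linspace(0, 1, 4000), fs=100.0)
        assert peaks.times.size == 1
        assert peaks.times[0] >= int(0.95 * 4000) - 100

    def test_constant_curve_empty(self):
        assert detect_peaks(np.zeros(4000), fs=100.0).times.size == 0

    def test_invariant_to_positive_affine_rescaling(self):
        tc = self._bumpy()
        a = detect_peaks(tc, fs=100.0).times
        b = detect_peaks(3.7 * tc + 11.0, fs=100.0).times
        np.testing.assert_array_equal(a, b)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(np.zeros(100), fs=100.0)


class TestBoundaryLocked:
    def test_planted_pre_boundary_effect_localized(self):
        rng = np.random.default_rng(4)
        n = 60000
        tc = 0.3 * rng.standard_normal(n)
        boundaries = np.arange(3000, 58000, 4500)
        for b in boundaries:
            tc[b - 140 : b - 120] += 3.0  # effect 1.2-1.4 s before the boundary
        out = boundary_locked(tc, 100.0, boundaries, window_s=(-3, 3),
                              n_perm=400, seed=0)
        sig_times = out["times_s"][out["mask"]]
        assert sig_times.size > 0
        assert np.all(sig_times >= -1.6) and np.all(sig_times <= -1.0)
        assert -1.45 < out["peak_s"] < -1.15

    def test_flat_curve_nothing_significant(self):
        out = boundary_locked(np.zeros(20000), 100.0,
                              np.array([5000, 9000, 13000]), n_perm=100, seed=1)
        assert not out["mask"].any()

    def test_too_few_boundaries_rejected(self):
        with pytest.raises(ValueError):
            boundary_locked(np.zeros(20000), 100.0, np.array([5000]))


class TestWordCorrelation:
    def _words(self, n_words, deltas, word_ms=300.0, gap_ms=100.0):
        onsets = np.arange(n_words) * (word_ms + gap_ms) + 1000.0
        return make_word_table(pd.DataFrame({
            "token": [f"w{i}" for i in range(n_words)],
            "onset_ms": onsets, "offset_ms": onsets + word_ms,
            "p_naive": 0.2, "p_exposed": np.clip(0.2 + deltas, 0, 1),
        }))

    def test_planted_lag_recovered(self):
        rng = np.random.default_rng(5)
        n_words = 80
        deltas = rng.uniform(-0.15, 0.6, n_words)
        words = self._words(n_words, deltas)
        n = 5000
        tc = 0.1 * rng.standard_normal(n)
        shift = 35  # neural response 350 ms after word onset
        for w in range(n_words):
            lo = int(words["onset_ms"].iloc[w] / 10) + shift
            hi = int(words["offset_ms"].iloc[w] / 10) + shift
            tc[lo:hi] += deltas[w]
        out = word_correlation(tc, 100.0, words,
                               lags_s=np.arange(-1.0, 1.01, 0.01),
                               n_perm=200, seed=0)
        assert abs(out["peak_lag_s"] - 0.35) <= 0.011
        assert out["mask"].any()

    def test_equal_deltas_flagged_degenerate(self):
        words = self._words(10, np.zeros(10))
        out = word_correlation(np.random.default_rng(6).standard_normal(2000),
                               100.0, words, n_perm=100, seed=0)
        assert out["degenerate"]

    def test_random_deltas_rarely_significant(self):
        rng = np.random.default_rng(7)
        n_sig = 0
        for seed in range(10):
            words = self._words(40, rng.normal(0, 0.1, 40))
            tc = rng.standard_normal(3000)
            out = word_correlation(tc, 100.0, words,
                                   lags_s=np.arange(-0.5, 0.51, 0.05),
                                   n_perm=200, seed=seed)
            n_sig += int(out["mask"].any())
        assert n_sig <= 2
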