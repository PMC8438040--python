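"""Moment-by-moment neural predictive recall from projected model predictions.

The directed VAR fits of the cross-run Granger analysis answer *whether* a
channel carries predictive information; this module asks *when*.  Only the
cross-run coefficient block of a fitted model is applied to the predictor
run,

    xhat'_t = sum_{k=1..p} A_xy,k * y_{t-k},

giving a partial forecast of run 1 built purely from run 2 (and vice versa).
Each partial forecast is projected onto the observed data (pointwise product,
averaged across the selected channels); the run-2->run-1 projection minus the
reverse is the predictive-recall time-course.  Peaks of this curve mark
moments the patient anticipates on the second listening.

Numerical conventions: the first p samples of a prediction are undefined and
dropped (not zero-filled); the moving-average smoother uses truncated
(shrinking) windows at the edges; Gaussian peak smoothing of nominal width w
uses sigma = w/6 truncated at +-3 sigma, so the support is +-w/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .stats import fdr_bh, perm_pvalue

__all__ = [
    "RecallTimecourse",
    "PeakSet",
    "partial_prediction",
    "projection",
    "recall_timecourse",
    "detect_peaks",
    "boundary_locked",
    "word_correlation",
]


@dataclass
class RecallTimecourse:
    """Smoothed projected-prediction difference at the analysis rate."""

    values: np.ndarray
    fs: float
    start_sample: int  # offset into the run: the first p samples are undefined
    channel_indices: np.ndarray
    per_channel: np.ndarray  # unsmoothed per-channel components, for SEM
    smoothing_width_s: float = 1.0

    def sem(self) -> np.ndarray:
        return self.per_channel.std(axis=0, ddof=1) / np.sqrt(self.per_channel.shape[0])


@dataclass
class PeakSet:
    """Cluster maxima of a thresholded, smoothed time-course."""

    times: np.ndarray  # sample indices into the source time-course
    fs: float
    smooth_s: float
    percentile: float
    source: str = "neural"

    @property
    def times_s(self) -> np.ndarray:
        return self.times / self.fs


def partial_prediction(a_cross: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Partial forecast using only the cross-run coefficients.

    Returns the prediction for t = p..n-1 (length n - p).
    """
    a = np.asarray(a_cross, dtype=float)
    y = np.asarray(y, dtype=float)
    p = a.size
    if y.size < p + 1:
        raise ValueError("series shorter than model order + 1")
    out = np.zeros(y.size - p)
    for k in range(1, p + 1):
        out += a[k - 1] * y[p - k : y.size - k]
    return out


def projection(pred: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Pointwise product of prediction and data, averaged across channels."""
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if pred.shape != data.shape:
        raise ValueError("prediction and data must have equal shape")
    return (pred * data).mean(axis=0)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with truncated windows at the edges."""
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    cnt = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / cnt


def recall_timecourse(run1, run2, results, channels: np.ndarray,
                      smooth_s: float = 1.0) -> RecallTimecourse:
    """Predictive-recall time-course over the selected (CPR) channels.

    ``results`` holds one fitted :class:`~storyrecall.granger.GCResult` per
    channel of the runs; only the channels in ``channels`` enter.  Each
    channel contributes (projected run2->run1 prediction) minus (projected
    run1->run2 prediction); the channel mean is smoothed with a centered 1 s
    moving average.
    """
    channels = np.asarray(channels, dtype=int)
    if channels.size < 1:
        raise ValueError("need at least one channel")
    p_common = max(results[c].order for c in channels)
    comps = []
    for c in channels:
        r = results[c]
        off = p_common - r.order
        xhat = partial_prediction(r.model_x.a_cross, run2.data[c] - run2.data[c].mean())[off:]
        yhat = partial_prediction(r.model_y.a_cross, run1.data[c] - run1.data[c].mean())[off:]
        x = run1.data[c][p_common:] - run1.data[c].mean()
        y = run2.data[c][p_common:] - run2.data[c].mean()
        comps.append(xhat * x - yhat * y)
    per_channel = np.vstack(comps)
    raw = per_channel.mean(axis=0)
    width = max(int(round(smooth_s * run1.fs)), 1)
    return RecallTimecourse(
        values=_moving_average(raw, width),
        fs=run1.fs,
        start_sample=p_common,
        channel_indices=channels,
        per_channel=per_channel,
        smoothing_width_s=smooth_s,
    )


def detect_peaks(tc: np.ndarray, fs: float, smooth_s: float = 2.0,
                 percentile: float = 95.0, source: str = "neural") -> PeakSet:
    """Local peaks: Gaussian smoothing, thresholding at a percentile, and one
    maximum per suprathreshold cluster (first sample on plateaus)."""
    x = np.asarray(tc, dtype=float)
    if x.size < 10 * smooth_s * fs:
        raise ValueError("time-course too short for the smoothing window")
    if np.ptp(x) == 0:
        return PeakSet(np.array([], dtype=int), fs, smooth_s, percentile, source)
    sigma = smooth_s / 6.0 * fs
    sm = gaussian_filter1d(x, sigma=sigma, truncate=3.0) if sigma > 0 else x
    thr = np.percentile(sm, percentile)
    above = sm > thr
    if not above.any():
        above = sm >= thr  # plateau at the threshold value
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    peaks = np.array([s + int(np.argmax(sm[s:e])) for s, e in zip(starts, ends)], dtype=int)
    return PeakSet(np.sort(peaks), fs, smooth_s, percentile, source)


def boundary_locked(tc: np.ndarray, fs: float, boundaries: np.ndarray,
                    window_s: tuple[float, float] = (-5.0, 5.0),
                    n_perm: int = 1000, seed: int = 0, q: float = 0.05) -> dict:
    """Event-locked average of the recall time-course around boundaries,
    against averages at equally many random boundary positions.

    Random draws stay one window half-width away from the story edges.  The
    per-timepoint p-value is the fraction of random averages at least as
    large as the observed one; significance is BH-FDR controlled over the
    window.
    """
    x = np.asarray(tc, dtype=float)
    b = np.asarray(boundaries, dtype=int)
    if b.size < 2:
        raise ValueError("need >= 2 boundaries")
    w0, w1 = int(round(window_s[0] * fs)), int(round(window_s[1] * fs))
    if b.min() + w0 < 0 or b.max() + w1 > x.size:
        raise ValueError("boundaries too close to the story edges for the window")
    offsets = np.arange(w0, w1)
    mean_curve = x[b[:, None] + offsets[None, :]].mean(axis=0)
    margin = max(-w0, w1)
    rng = np.random.default_rng(seed)
    draws = rng.integers(margin, x.size - margin, size=(n_perm, b.size))
    null = x[draws[:, :, None] + offsets[None, None, :]].mean(axis=1)
    p = (null >= mean_curve[None, :]).mean(axis=0)
    fdr = fdr_bh(p, q=q)
    return {
        "times_s": offsets / fs,
        "mean_curve": mean_curve,
        "null_mean": null.mean(axis=0),
        "null_lo": np.percentile(null, 5, axis=0),
        "null_hi": np.percentile(null, 95, axis=0),
        "p": p,
        "mask": fdr["mask"],
        "p_fdr": fdr["p_fdr"],
        "peak_s": float(offsets[np.argmax(mean_curve)] / fs),
    }


def word_correlation(tc: np.ndarray, fs: float, words, lags_s: np.ndarray | None = None,
                     n_perm: int = 1000, seed: int = 0, q: float = 0.05,
                     tc_offset_ms: float = 0.0) -> dict:
    """Correlation of behavioral word-learning with the neural recall curve.

    A behavioral vector holds each word's prediction-probability change at
    the samples where the word is heard; the Pearson correlation with the
    neural curve is computed *only* over word samples (silences excluded) at
    every shift of the time axis.  The null reassigns the per-word changes
    randomly to the words.  ``tc_offset_ms`` is the story time of the first
    time-course sample (predictions drop the initial p samples).
    """
    x = np.asarray(tc, dtype=float)
    if lags_s is None:
        lags_s = np.arange(-2.0, 2.0 + 1e-9, 0.01)
    lag_samps = np.round(np.asarray(lags_s) * fs).astype(int)
    deltas = words["delta"].to_numpy(dtype=float)
    if np.ptp(deltas) == 0:
        return {"lags_s": np.asarray(lags_s), "r": None, "degenerate": True}
    onset = np.round((words["onset_ms"].to_numpy() - tc_offset_ms) * fs / 1000.0).astype(int)
    offset = np.round((words["offset_ms"].to_numpy() - tc_offset_ms) * fs / 1000.0).astype(int)
    word_idx = [np.arange(max(o, 0), min(f, x.size)) for o, f in zip(onset, offset)]
    word_of_sample = np.concatenate(
        [np.full(ix.size, w) for w, ix in enumerate(word_idx)]
    )
    samples = np.concatenate(word_idx)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(deltas.size) for _ in range(n_perm)])
    n_words = deltas.size
    rs = np.full(lag_samps.size, np.nan)
    null_rs = np.full((n_perm, lag_samps.size), np.nan)
    counts = np.bincount(word_of_sample, minlength=n_words).astype(float)
    for i, L in enumerate(lag_samps):
        valid = (samples + L >= 0) & (samples + L < x.size)
        if not valid.any():
            continue
        neu = x[samples[valid] + L]
        wos = word_of_sample[valid]
        n_s = neu.size
        s_w = np.bincount(wos, weights=neu, minlength=n_words)
        m_w = np.bincount(wos, minlength=n_words).astype(float)
        mean_n = neu.mean()
        var_n = neu.var()
        if var_n == 0:
            continue

        def _r(dv: np.ndarray) -> np.ndarray:
            mean_b = dv @ m_w / n_s
            var_b = (dv**2) @ m_w / n_s - mean_b**2
            cov = dv @ s_w / n_s - mean_b * mean_n
            return cov / np.sqrt(var_b * var_n)

        rs[i] = float(_r(deltas))
        null_rs[:, i] = _r(deltas[perms])  # _r broadcasts over (n_perm, n_words)
    p = np.nanmean(null_rs >= rs[None, :], axis=0)
    ok = np.isfinite(rs)
    fdr = fdr_bh(p[ok], q=q)
    mask = np.zeros_like(ok)
    mask[ok] = fdr["mask"]
    peak = int(np.nanargmax(rs))
    return {
        "lags_s": np.asarray(lags_s),
        "r": rs,
        "p": p,
        "mask": mask,
        "p_fdr": fdr["p_fdr"],
        "peak_lag_s": float(np.asarray(lags_s)[peak]),
        "r_peak": float(rs[peak]),
        "degenerate": False,
    }
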