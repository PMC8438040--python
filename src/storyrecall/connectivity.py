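"""Lagged Gaussian-copula mutual information between cortex and hippocampus.

Shared information between the multivariate high-gamma pattern on the
cortical predictive-recall (CPR) channels and a target channel's feature
stack is estimated with Gaussian-copula mutual information (GCMI): every
dimension is rank-transformed to normal quantiles (rank/(n+1), average ranks
on ties, then the inverse normal CDF), after which Gaussian (conditional) MI
follows from covariance log-determinants with an analytic small-sample bias
correction.  The estimate is a lower bound of the true MI and is exactly
invariant to strictly monotone transforms of each input dimension.

Information *flow* is resolved by shifting the target against the CPR
pattern over a grid of lags (positive lag = target lags behind cortex,
negative = target leads) and conditioning each lagged estimate on the
unshifted target pattern to remove instantaneous, typically spurious, shared
signal.  Around event boundaries the procedure is repeated at a grid of
distances from the boundary, giving a 2-D lag x distance map; around recall
peaks a single 1-D lag profile is computed.  Significance uses cluster-based
channel-swap permutations (maps) and phase-shuffled peak selections
(profiles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps
from scipy.special import ndtri, psi

from .stats import fdr_bh, perm_pvalue, phase_shuffle
from .timecourse import detect_peaks

__all__ = [
    "MIMap",
    "ClusterStat",
    "copula_mi",
    "conditional_copula_mi",
    "lagged_profile",
    "boundary_map",
    "cluster_perm_maps",
    "peak_locked_mi",
]


@dataclass
class MIMap:
    """Conditional-MI surface over channel lag x distance-to-boundary."""

    mi: np.ndarray  # (n_lags, n_distances)
    lag_grid: np.ndarray  # samples; positive = target lags behind cortex
    distance_grid: np.ndarray  # samples relative to the boundary
    fs: float
    roi: str = ""
    run: int = 0
    conditioning: str = "zero-lag"

    def __post_init__(self) -> None:
        if self.mi.shape != (self.lag_grid.size, self.distance_grid.size):
            raise ValueError("mi shape must be (n_lags, n_distances)")


@dataclass
class ClusterStat:
    """Cluster-based channel-swap permutation result on a pair of map sets."""

    clusters: list[dict]
    max_sum: float
    p_perm: float
    t_map: np.ndarray
    t_threshold: float


def _copula_normalize(X: np.ndarray) -> np.ndarray:
    """Per-dimension rank -> normal-quantile transform of a (d, n) array."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d, n = X.shape
    out = np.empty_like(X)
    for i in range(d):
        if np.ptp(X[i]) == 0:
            raise ValueError(f"constant dimension {i}: copula transform undefined")
        ranks = sps.rankdata(X[i], method="average")
        out[i] = ndtri(ranks / (n + 1))
    return out


def _gauss_ent(X: np.ndarray, biascorrect: bool = True) -> float:
    """Differential entropy (nats) of a Gaussian fitted to (d, n) data, with
    the analytic expected-log-determinant bias correction."""
    X = np.atleast_2d(X)
    d, n = X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    C = Xc @ Xc.T / (n - 1)
    # tiny ridge keeps the log-determinant finite when dimensions coincide
    # exactly (e.g. the zero-lag conditioner at lag 0); on the unit-variance
    # copula scale it leaves regular estimates untouched
    C[np.diag_indices_from(C)] += 1e-9
    chol = np.linalg.cholesky(C)
    h = float(np.sum(np.log(np.diag(chol)))) + 0.5 * d * (np.log(2.0 * np.pi) + 1.0)
    if biascorrect:
        psiterms = psi((n - np.arange(1, d + 1)) / 2.0) / 2.0
        dterm = (np.log(2.0 / (n - 1.0))) / 2.0
        h -= d * dterm + float(psiterms.sum())
    return h


def copula_mi(x: np.ndarray, y: np.ndarray, biascorrect: bool = True) -> float:
    """Gaussian-copula MI (nats) between two multivariate sample sets (d, n)."""
    cx = _copula_normalize(x)
    cy = _copula_normalize(y)
    if cx.shape[1] != cy.shape[1]:
        raise ValueError("x and y must have the same number of samples")
    if cx.shape[1] < 50:
        raise ValueError("need >= 50 samples for a stable copula MI estimate")
    return (
        _gauss_ent(cx, biascorrect)
        + _gauss_ent(cy, biascorrect)
        - _gauss_ent(np.vstack([cx, cy]), biascorrect)
    )


def conditional_copula_mi(x: np.ndarray, y: np.ndarray, z: np.ndarray,
                          biascorrect: bool = True) -> float:
    """Gaussian-copula conditional MI I(X;Y|Z) in nats."""
    cx = _copula_normalize(x)
    cy = _copula_normalize(y)
    cz = _copula_normalize(z)
    n = cx.shape[1]
    if not (cy.shape[1] == n == cz.shape[1]):
        raise ValueError("x, y, z must have the same number of samples")
    if n < 50:
        raise ValueError("need >= 50 samples for a stable copula MI estimate")
    return (
        _gauss_ent(np.vstack([cx, cz]), biascorrect)
        + _gauss_ent(np.vstack([cy, cz]), biascorrect)
        - _gauss_ent(np.vstack([cx, cy, cz]), biascorrect)
        - _gauss_ent(cz, biascorrect)
    )


def _window_samples(windows, n: int) -> np.ndarray:
    idx_parts = []
    for lo, hi in windows:
        lo_i, hi_i = int(lo), int(hi)
        if lo_i < 0 or hi_i > n:
            warnings.warn(f"window ({lo}, {hi}) exceeds the data span; dropped", stacklevel=3)
            continue
        idx_parts.append(np.arange(lo_i, hi_i))
    if not idx_parts:
        raise ValueError("no valid windows inside the data span")
    return np.concatenate(idx_parts)


def lagged_profile(cpr: np.ndarray, target: np.ndarray, windows,
                   lag_grid: np.ndarray, condition_zero_lag: bool = True) -> np.ndarray:
    """Conditional MI between the CPR pattern and a shifted target, per lag.

    Samples are concatenated across the given windows; at each lag the target
    features are shifted by that many samples (positive = target lags behind
    the cortical pattern) and the MI is conditioned on the unshifted target
    features.  Returns one MI value (nats) per grid lag.
    """
    cpr = np.atleast_2d(np.asarray(cpr, dtype=float))
    target = np.atleast_2d(np.asarray(target, dtype=float))
    n = cpr.shape[1]
    if target.shape[1] != n:
        raise ValueError("cpr and target must share the time axis")
    idx = _window_samples(windows, n)
    lag_grid = np.asarray(lag_grid, dtype=int)
    out = np.empty(lag_grid.size)
    for i, L in enumerate(lag_grid):
        valid = idx[(idx + L >= 0) & (idx + L < n)]
        x = cpr[:, valid]
        y = target[:, valid + L]
        if condition_zero_lag:
            out[i] = conditional_copula_mi(x, y, target[:, valid])
        else:
            out[i] = copula_mi(x, y)
    return out


def boundary_map(cpr: np.ndarray, target: np.ndarray, boundaries: np.ndarray,
                 fs: float, distance_grid: np.ndarray, lag_grid: np.ndarray,
                 window_s: float = 1.0, roi: str = "", run: int = 0,
                 condition_zero_lag: bool = True) -> MIMap:
    """2-D MI map around event boundaries.

    For every distance d in the grid, 1 s windows are centered at
    boundary + d and the full lag profile is computed on their concatenated
    samples.  Grids are in samples at ``fs``.
    """
    boundaries = np.asarray(boundaries, dtype=int)
    half = int(round(window_s * fs / 2.0))
    distance_grid = np.asarray(distance_grid, dtype=int)
    lag_grid = np.asarray(lag_grid, dtype=int)
    mi = np.empty((lag_grid.size, distance_grid.size))
    for j, dist in enumerate(distance_grid):
        windows = [(b + dist - half, b + dist + half) for b in boundaries]
        mi[:, j] = lagged_profile(cpr, target, windows, lag_grid, condition_zero_lag)
    return MIMap(mi, lag_grid, distance_grid, fs, roi=roi, run=run,
                 conditioning="zero-lag" if condition_zero_lag else "none")


def _t_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pointwise pooled-variance two-sample t between two (n, ...) stacks."""
    n1, n2 = a.shape[0], b.shape[0]
    df = n1 + n2 - 2
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    pooled = ((n1 - 1) * va + (n2 - 1) * vb) / df
    denom = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / denom
    return np.where(np.isfinite(t), t, 0.0)


def _max_cluster_sum(t: np.ndarray, roi_mean: np.ndarray, threshold: float,
                     mask: np.ndarray) -> tuple[float, list[dict]]:
    supra = (t > threshold) & mask
    labels, n_lab = ndimage.label(supra)  # 4-connected on the 2-D grid
    clusters = []
    for lab in range(1, n_lab + 1):
        sel = labels == lab
        clusters.append({"mask": sel, "mi_sum": float(roi_mean[sel].sum()),
                         "size": int(sel.sum())})
    max_sum = max((c["mi_sum"] for c in clusters), default=0.0)
    return max_sum, clusters


def cluster_perm_maps(maps_roi: np.ndarray, maps_control: np.ndarray,
                      n_perm: int = 1000, seed: int = 0, alpha: float = 0.05,
                      plausible_mask: np.ndarray | None = None) -> ClusterStat:
    """Cluster-based permutation contrast of ROI vs control MI maps.

    ``maps_roi`` and ``maps_control`` stack per-channel maps (n_ch, L, D).
    Clusters are 4-connected points inside the plausible window whose
    pointwise two-sample t (ROI > control) exceeds the one-tailed 95th
    percentile; the statistic is the summed ROI-mean MI inside the cluster.
    The null randomly swaps channels between the two groups.
    """
    a = np.asarray(maps_roi, dtype=float)
    b = np.asarray(maps_control, dtype=float)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("ROI and control maps must share the grid")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 channels per ROI")
    mask = np.ones(a.shape[1:], dtype=bool) if plausible_mask is None else plausible_mask
    df = a.shape[0] + b.shape[0] - 2
    thr = float(sps.t.ppf(1.0 - alpha, df))
    t_obs = _t_map(a, b)
    obs_sum, clusters = _max_cluster_sum(t_obs, a.mean(axis=0), thr, mask)
    pooled = np.concatenate([a, b], axis=0)
    n1 = a.shape[0]
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        pa, pb = pooled[perm[:n1]], pooled[perm[n1:]]
        null[i], _ = _max_cluster_sum(_t_map(pa, pb), pa.mean(axis=0), thr, mask)
    p = perm_pvalue(obs_sum, null) if clusters else 1.0
    return ClusterStat(clusters=clusters, max_sum=obs_sum, p_perm=p,
                       t_map=t_obs, t_threshold=thr)


def _profiles_for_peaks(cpr_by_run: dict, targets_by_run: dict, peak_samples: np.ndarray,
                        fs: float, lag_grid: np.ndarray, window_s: float) -> dict:
    half = int(round(window_s * fs / 2.0))
    windows = [(pk - half, pk + half) for pk in peak_samples]
    out = {}
    for run, cpr in cpr_by_run.items():
        out[run] = np.vstack([
            lagged_profile(cpr, tgt, windows, lag_grid) for tgt in targets_by_run[run]
        ])
    return out


def peak_locked_mi(cpr_by_run: dict, hippo_targets_by_run: dict,
                   other_targets_by_run: dict, tc_values: np.ndarray, tc_fs: float,
                   tc_start: int, lag_grid: np.ndarray, fs: float,
                   window_s: float = 1.0, n_perm: int = 200, seed: int = 0,
                   q: float = 0.05, smooth_s: float = 2.0,
                   percentile: float = 95.0) -> dict:
    """Lag profiles of hippocampo-cortical MI locked to recall peaks, with the
    four contrasts reported around such profiles.

    Peaks are detected on the predictive-recall time-course ``tc_values``
    (whose sample 0 is run sample ``tc_start``).  For each run, per-channel
    lag profiles are computed over 1 s windows around the peaks, for the
    hippocampal group and the control ("other") group.  Contrasts, each
    BH-FDR corrected over lags:

    1. run-wise hippocampal mean vs profiles from peaks of phase-shuffled
       time-courses;
    2. hippocampus vs other channels (two-tailed independent t);
    3. hippocampal run 2 vs run 1 (two-tailed dependent t);
    4. hippocampal run difference vs phase-shuffled run differences.
    """
    runs = sorted(cpr_by_run)
    peaks = detect_peaks(tc_values, tc_fs, smooth_s=smooth_s, percentile=percentile)
    if peaks.times.size < 5:
        raise ValueError("need >= 5 recall peaks")
    peak_samples = peaks.times + tc_start
    hippo = _profiles_for_peaks(cpr_by_run, hippo_targets_by_run, peak_samples,
                                fs, lag_grid, window_s)
    other = _profiles_for_peaks(cpr_by_run, other_targets_by_run, peak_samples,
                                fs, lag_grid, window_s)

    rng = np.random.default_rng(seed)
    null_mean = {r: np.empty((n_perm, lag_grid.size)) for r in runs}
    done = 0
    attempts = 0
    while done < n_perm:
        attempts += 1
        if attempts > 20 * n_perm:  # pragma: no cover - pathological inputs
            raise RuntimeError("phase-shuffled surrogates keep yielding < 2 peaks")
        sur = phase_shuffle(tc_values, 1, rng)[0]
        sp = detect_peaks(sur, tc_fs, smooth_s=smooth_s, percentile=percentile)
        if sp.times.size < 2:
            continue  # redraw
        sur_profiles = _profiles_for_peaks(cpr_by_run, hippo_targets_by_run,
                                           sp.times + tc_start, fs, lag_grid, window_s)
        for r in runs:
            null_mean[r][done] = sur_profiles[r].mean(axis=0)
        done += 1

    out: dict = {"peaks": peaks, "lag_grid": lag_grid,
                 "hippo_profiles": hippo, "other_profiles": other}
    for r in runs:
        obs = hippo[r].mean(axis=0)
        p_shuf = (null_mean[r] >= obs[None, :]).mean(axis=0)
        fdr_shuf = fdr_bh(p_shuf, q=q)
        t_vs_other = _t_map(hippo[r], other[r])
        df = hippo[r].shape[0] + other[r].shape[0] - 2
        p_other = 2.0 * sps.t.sf(np.abs(t_vs_other), df)
        fdr_other = fdr_bh(p_other, q=q)
        out[f"run{r}"] = {
            "mean": obs,
            "null_mean": null_mean[r].mean(axis=0),
            "null_hi": np.percentile(null_mean[r], 95, axis=0),
            "p_vs_shuffled": p_shuf, "mask_vs_shuffled": fdr_shuf["mask"],
            "p_fdr_vs_shuffled": fdr_shuf["p_fdr"],
            "p_vs_other": p_other, "mask_vs_other": fdr_other["mask"],
            "p_fdr_vs_other": fdr_other["p_fdr"],
            "conjunction": fdr_shuf["mask"] & fdr_other["mask"],
        }
    if len(runs) == 2:
        r1, r2 = runs
        d_h = hippo[r2] - hippo[r1]
        n_h = d_h.shape[0]
        sd = d_h.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_run = d_h.mean(axis=0) / (sd / np.sqrt(n_h))
        t_run = np.where(np.isfinite(t_run), t_run, 0.0)
        p_run = 2.0 * sps.t.sf(np.abs(t_run), n_h - 1)
        fdr_run = fdr_bh(p_run, q=q)
        null_diff = null_mean[r2] - null_mean[r1]
        obs_diff = d_h.mean(axis=0)
        p_diff = (null_diff >= obs_diff[None, :]).mean(axis=0)
        fdr_diff = fdr_bh(p_diff, q=q)
        out["run_contrast"] = {
            "mean_diff": obs_diff,
            "p_run2_gt_run1": p_run, "mask_run2_gt_run1": fdr_run["mask"],
            "p_fdr_run2_gt_run1": fdr_run["p_fdr"],
            "p_diff_vs_shuffled": p_diff, "mask_diff_vs_shuffled": fdr_diff["mask"],
            "p_fdr_diff_vs_shuffled": fdr_diff["p_fdr"],
            "conjunction": fdr_run["mask"] & fdr_diff["mask"],
        }
    return out
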