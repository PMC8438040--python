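"""Behavioral analyses of event segmentation and word-prediction learning.

Raters listen to a spoken story twice and press a key whenever one natural
and meaningful unit of the story ends and another begins.  Each rater's
responses are coded as a binary vector at 1 kHz (1 wherever a press falls
within the surrounding second), and the across-rater mean of these vectors is
the *agreement time-course*: the proportion of raters perceiving each moment
as an event boundary.  Learning after a single exposure shows up in two ways:
raters agree more with each other on the second run (consensus learning), and
their responses come earlier (a negative lag of the run-2 agreement curve
relative to run 1).

A separate word-prediction task yields, for every word of the story, the
probability that naive vs. previously-exposed participants predict it; the
per-word increase is the behavioral measure of predictive recall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import cohens_d, perm_pvalue, t_dep, t_ind

__all__ = [
    "PressLog",
    "AgreementTimecourse",
    "make_word_table",
    "code_response_vector",
    "agreement",
    "consensus_cosine",
    "consensus_learning_test",
    "crosscorr_lag",
    "run_label_perm_lag",
    "boundary_peaks_from_agreement",
    "word_learning_contrast",
    "participant_contrast",
    "exclude_dissimilar",
]


@dataclass
class PressLog:
    """One rater's button presses for one run, in ms from story onset."""

    participant_id: str
    run: int
    press_times: np.ndarray
    story_duration: int  # ms

    def __post_init__(self) -> None:
        self.press_times = np.sort(np.asarray(self.press_times, dtype=float))
        if self.run not in (1, 2):
            raise ValueError("run must be 1 or 2")
        if self.story_duration <= 0:
            raise ValueError("story_duration must be positive")


@dataclass
class AgreementTimecourse:
    """Proportion of raters marking each millisecond as an event boundary."""

    values: np.ndarray
    run: int
    n_participants: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < -1e-12) | (self.values > 1 + 1e-12)):
            raise ValueError("agreement values must lie in [0, 1]")


WORD_COLUMNS = ("token", "onset_ms", "offset_ms", "p_naive", "p_exposed")


def make_word_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-word table and add the learning column ``delta``.

    Expects columns token, onset_ms, offset_ms, p_naive, p_exposed; words must
    be sorted, non-overlapping, with onset < offset and probabilities in
    [0, 1].
    """
    missing = [c for c in WORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"word table missing columns: {missing}")
    df = df.copy()
    if np.any(df["onset_ms"].to_numpy() >= df["offset_ms"].to_numpy()):
        raise ValueError("every word needs onset < offset")
    if np.any(np.diff(df["onset_ms"].to_numpy()) <= 0):
        raise ValueError("words must be sorted by onset")
    if np.any(df["offset_ms"].to_numpy()[:-1] > df["onset_ms"].to_numpy()[1:]):
        raise ValueError("words must not overlap")
    for col in ("p_naive", "p_exposed"):
        p = df[col].to_numpy(dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError(f"{col} must lie in [0, 1]")
    df["delta"] = df["p_exposed"] - df["p_naive"]
    return df


def code_response_vector(log: PressLog, window_ms: int = 1000) -> np.ndarray:
    """Binary 1 kHz response vector: 1 wherever a press lies within the
    surrounding second (±window/2, half-open on the right)."""
    if window_ms % 2 != 0:
        raise ValueError("window_ms must be even to split symmetrically")
    half = window_ms // 2
    n = int(log.story_duration)
    vec = np.zeros(n, dtype=np.uint8)
    times = log.press_times
    inside = (times >= 0) & (times <= n)
    if not np.all(inside):
        warnings.warn(
            f"{(~inside).sum()} press(es) outside the story dropped "
            f"(participant {log.participant_id}, run {log.run})",
            stacklevel=2,
        )
        times = times[inside]
    for t in times:
        lo = max(int(np.floor(t)) - half, 0)
        hi = min(int(np.floor(t)) + half, n)
        vec[lo:hi] = 1
    return vec


def agreement(vectors: np.ndarray | list, run: int = 0) -> AgreementTimecourse:
    """Across-participant mean of binary response vectors."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] == 0:
        raise ValueError("need a non-empty participants x time matrix")
    return AgreementTimecourse(vectors.mean(axis=0), run, vectors.shape[0])


def consensus_cosine(v: np.ndarray, others_mean: np.ndarray) -> float:
    """Cosine similarity of a response vector to the mean of all others.

    Returns 0.0 (with a warning) if either vector has zero norm.
    """
    v = np.asarray(v, dtype=float)
    m = np.asarray(others_mean, dtype=float)
    if v.shape != m.shape:
        raise ValueError("length mismatch between response vector and mean")
    nv = np.linalg.norm(v)
    nm = np.linalg.norm(m)
    if nv == 0.0 or nm == 0.0:
        warnings.warn("zero-norm vector in consensus_cosine; returning 0", stacklevel=2)
        return 0.0
    return float(np.dot(v, m) / (nv * nm))


def _loo_cosines_from_gram(G: np.ndarray) -> np.ndarray:
    """Leave-one-out cosines from a Gram matrix of response vectors.

    cos_i = <v_i, S - v_i> / (||v_i|| ||S - v_i||) with S the sum of all
    vectors; the normalisation by (n-1) of the mean cancels in the cosine.
    """
    diag = np.diag(G)
    rows = G.sum(axis=1)
    total = G.sum()
    num = rows - diag
    nrm_other_sq = total - 2.0 * rows + diag
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / np.sqrt(diag * nrm_other_sq)
    out[~np.isfinite(out)] = 0.0
    return out


def _gram_blocks(v1: np.ndarray, v2: np.ndarray):
    V1 = v1.astype(float)
    V2 = v2.astype(float)
    return V1 @ V1.T, V1 @ V2.T, V2 @ V2.T


def _flipped_grams(G11, G12, G22, flips):
    """Gram matrices of the run-1 and run-2 vector sets after swapping the run
    labels of the flipped participants."""
    f = flips.astype(bool)
    a = np.where(f[:, None], np.where(f[None, :], G22, G12.T), np.where(f[None, :], G12, G11))
    b = np.where(f[:, None], np.where(f[None, :], G11, G12), np.where(f[None, :], G12.T, G22))
    return a, b


def consensus_learning_test(logs_run1: list[PressLog], logs_run2: list[PressLog],
                            n_perm: int = 1000, seed: int = 0) -> dict:
    """Test whether leave-one-out consensus increases from run 1 to run 2.

    The observed across-participant mean of (run-2 cosine − run-1 cosine) is
    compared to its distribution under independent per-participant swaps of
    the run labels; a one-sided binomial test additionally asks whether the
    number of improving participants exceeds chance (P(improve) = 0.5).
    """
    if len(logs_run1) != len(logs_run2) or len(logs_run1) < 2:
        raise ValueError("need the same >= 2 participants in both runs")
    V1 = np.stack([code_response_vector(lg) for lg in logs_run1]).astype(float)
    V2 = np.stack([code_response_vector(lg) for lg in logs_run2]).astype(float)
    G11, G12, G22 = _gram_blocks(V1, V2)
    n = V1.shape[0]
    cos1 = _loo_cosines_from_gram(G11)
    cos2 = _loo_cosines_from_gram(G22)
    diffs = cos2 - cos1
    mean_diff = float(diffs.mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        flips = rng.integers(0, 2, size=n)
        Ga, Gb = _flipped_grams(G11, G12, G22, flips)
        null[i] = (_loo_cosines_from_gram(Gb) - _loo_cosines_from_gram(Ga)).mean()
    n_improved = int(np.sum(diffs > 0))
    p_binom = float(sps.binomtest(n_improved, n, 0.5, alternative="greater").pvalue)
    return {
        "mean_diff": mean_diff,
        "cos_run1": cos1,
        "cos_run2": cos2,
        "p_perm": perm_pvalue(mean_diff, null),
        "n_improved": n_improved,
        "p_binomial": p_binom,
    }


def crosscorr_lag(tc2: AgreementTimecourse | np.ndarray,
                  tc1: AgreementTimecourse | np.ndarray,
                  max_lag_ms: int = 1000) -> dict:
    """Lag maximizing the Pearson correlation between two agreement curves.

    At each integer-ms lag L the run-2 curve shifted by L is correlated with
    the run-1 curve over the overlapping samples.  A negative best lag means
    run-2 responses occur *earlier* than run-1 responses.
    """
    a = tc2.values if isinstance(tc2, AgreementTimecourse) else np.asarray(tc2, float)
    b = tc1.values if isinstance(tc1, AgreementTimecourse) else np.asarray(tc1, float)
    if a.shape != b.shape:
        raise ValueError("agreement curves must have equal length")
    n = a.size
    if max_lag_ms >= n // 4:
        raise ValueError("max_lag_ms must be below a quarter of the duration")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant input: correlation undefined")
    lags = np.arange(-max_lag_ms, max_lag_ms + 1)
    rs = np.empty(lags.size)
    for i, L in enumerate(lags):
        if L >= 0:
            x, y = a[L:], b[: n - L]
        else:
            x, y = a[: n + L], b[-L:]
        xm = x - x.mean()
        ym = y - y.mean()
        denom = np.sqrt((xm @ xm) * (ym @ ym))
        rs[i] = (xm @ ym) / denom if denom > 0 else np.nan
    best = int(np.nanargmax(rs))
    return {"r_max": float(rs[best]), "lag_ms": int(lags[best]), "lags": lags, "r": rs}


def run_label_perm_lag(logs_run1: list[PressLog], logs_run2: list[PressLog],
                       max_lag_ms: int = 1000, n_perm: int = 1000,
                       seed: int = 0) -> dict:
    """Permutation test of the observed run-2 vs run-1 cross-correlation lag.

    Each permutation independently swaps each participant's run labels,
    recomputes the two average curves and their best lag; p is the fraction
    of permuted |lags| at least as large as the observed |lag|.
    """
    if len(logs_run1) != len(logs_run2) or len(logs_run1) < 2:
        raise ValueError("need the same >= 2 participants in both runs")
    V1 = np.stack([code_response_vector(lg) for lg in logs_run1]).astype(float)
    V2 = np.stack([code_response_vector(lg) for lg in logs_run2]).astype(float)
    n = V1.shape[0]
    S1, S2 = V1.sum(axis=0), V2.sum(axis=0)
    D = V2 - V1
    obs = crosscorr_lag(S2 / n, S1 / n, max_lag_ms)
    rng = np.random.default_rng(seed)
    null_lags = np.empty(n_perm)
    for i in range(n_perm):
        flips = rng.integers(0, 2, size=n).astype(float)
        shift = flips @ D
        null_lags[i] = crosscorr_lag((S2 - shift) / n, (S1 + shift) / n, max_lag_ms)["lag_ms"]
    p = perm_pvalue(abs(obs["lag_ms"]), np.abs(null_lags))
    return {"lag_ms": obs["lag_ms"], "r_max": obs["r_max"], "p": p, "null_lags": null_lags}


def boundary_peaks_from_agreement(tc: AgreementTimecourse, smooth_s: float = 2.0,
                                  percentile: float = 95.0) -> np.ndarray:
    """Event-boundary times (ms) as local peaks of the agreement curve."""
    from .timecourse import detect_peaks

    peaks = detect_peaks(tc.values, fs=1000.0, smooth_s=smooth_s, percentile=percentile)
    return peaks.times.astype(int)


def word_learning_contrast(table: pd.DataFrame) -> dict:
    """Paired t-test across words of exposed vs naive prediction probability;
    d = t/sqrt(N) with N the number of words."""
    if len(table) < 2:
        raise ValueError("need at least two words")
    res = t_dep(table["p_exposed"].to_numpy(), table["p_naive"].to_numpy())
    res["d"] = cohens_d(res["t"], len(table), "dependent")
    return res


def participant_contrast(correct_counts_exposed: np.ndarray,
                         correct_counts_naive: np.ndarray) -> dict:
    """Independent-sample t-test of per-participant correct-prediction counts
    between the exposed and naive groups; d = 2t/sqrt(df)."""
    res = t_ind(correct_counts_exposed, correct_counts_naive)
    res["d"] = cohens_d(res["t"], res["df"], "independent")
    return res


def exclude_dissimilar(matrix: np.ndarray, threshold: float,
                       iterative: bool = True) -> np.ndarray:
    """Indices of participants retained after similarity-based exclusion.

    A participant is excluded when the cosine similarity of their response row
    to the average row of all remaining others is <= ``threshold``.  The
    iterative variant repeats the pass on the reduced set until stable (used
    for the word-prediction replication, threshold 0.6); the single-pass
    variant is used for segmentation outliers (threshold 0.15).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    M = np.asarray(matrix, dtype=float)
    keep = np.arange(M.shape[0])
    while True:
        sub = M[keep]
        if sub.shape[0] < 2:
            raise ValueError("exclusion removed (almost) all participants")
        colsum = sub.sum(axis=0)
        sims = np.array(
            [consensus_cosine(row, (colsum - row) / (sub.shape[0] - 1)) for row in sub]
        )
        bad = sims <= threshold
        if not bad.any():
            return keep
        if bad.all():
            raise ValueError("exclusion removed all participants")
        keep = keep[~bad]
        if not iterative:
            return keep
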