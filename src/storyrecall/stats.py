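"""Shared statistical machinery: surrogates, FDR control, t-tests, effect sizes.

Permutation p-values are reported, by convention, as the plain count of null
statistics at least as extreme as the observed one divided by the number of
permutations (no +1 smoothing); a smoothed variant is available everywhere a
p-value is produced via ``smoothed=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SurrogateSpec",
    "perm_pvalue",
    "phase_shuffle",
    "fdr_bh",
    "t_dep",
    "t_ind",
    "t_ind_from_stats",
    "cohens_d",
]

_SURROGATE_METHODS = frozenset(
    {
        "phase_shuffle",
        "run_label_swap",
        "sign_flip",
        "random_boundaries",
        "delta_reassign",
        "channel_swap",
    }
)


@dataclass(frozen=True)
class SurrogateSpec:
    """Declaration of a permutation/surrogate scheme.

    Every permutation-based p-value in the package flows through one of the
    methods named here and is reproducible bit-exactly from ``seed``.
    """

    method: str
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in _SURROGATE_METHODS:
            raise ValueError(f"unknown surrogate method {self.method!r}")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100 for any reported p-value")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def perm_pvalue(observed: float, null: np.ndarray, *, alternative: str = "greater",
                smoothed: bool = False) -> float:
    """p-value of ``observed`` against a permutation ``null`` distribution.

    alternative: 'greater' counts null >= observed, 'less' counts null <=
    observed, 'two-sided' counts |null| >= |observed|.
    """
    null = np.asarray(null, dtype=float)
    if alternative == "greater":
        count = int(np.sum(null >= observed))
    elif alternative == "less":
        count = int(np.sum(null <= observed))
    elif alternative == "two-sided":
        count = int(np.sum(np.abs(null) >= abs(observed)))
    else:  # pragma: no cover - defensive
        raise ValueError(f"unknown alternative {alternative!r}")
    n = null.size
    if smoothed:
        return (count + 1) / (n + 1)
    return count / n


def phase_shuffle(x: np.ndarray, n_surrogates: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Phase-randomized surrogates of a real series.

    The discrete-Fourier amplitude spectrum is preserved exactly (hence the
    autocorrelation structure), while the phases of the positive frequencies
    are drawn uniformly; DC and (for even length) Nyquist terms stay real.

    Returns an ``(n_surrogates, len(x))`` array.
    """
    x = np.asarray(x)
    if np.iscomplexobj(x):
        raise ValueError("phase_shuffle requires a real-valued series")
    x = x.astype(float)
    n = x.size
    if n < 16:
        raise ValueError("series too short for meaningful phase shuffling (need >= 16)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = np.fft.rfft(x)
    mag = np.abs(spec)
    n_freq = spec.size
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_surrogates, n_freq))
    phases[:, 0] = 0.0  # DC stays real and positive
    if n % 2 == 0:
        # Nyquist bin of an even-length real FFT must stay real; keep its sign.
        phases[:, -1] = 0.0 if spec[-1].real >= 0 else np.pi
        mag = mag.copy()
        mag[-1] = np.abs(spec[-1])
    sur_spec = mag[None, :] * np.exp(1j * phases)
    sur_spec[:, 0] = spec[0]
    return np.fft.irfft(sur_spec, n=n, axis=1)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> dict:
    """Benjamini–Hochberg step-up FDR control.

    Returns ``{"mask": boolean array, "p_fdr": largest significant raw p or
    nan, "p_adjusted": BH-adjusted p-values}``.  ``p_fdr`` is the value
    conventionally reported: every significant raw p-value is <= p_fdr.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    mask, p_adj, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    mask = mask.reshape(p.shape)
    p_adj = p_adj.reshape(p.shape)
    p_fdr = float(p[mask].max()) if mask.any() else float("nan")
    return {"mask": mask, "p_fdr": p_fdr, "p_adjusted": p_adj}


def t_dep(a: np.ndarray, b: np.ndarray) -> dict:
    """Two-tailed dependent (paired) sample t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero variance of paired differences; t undefined")
    res = sps.ttest_rel(a, b)
    return {"t": float(res.statistic), "df": int(a.size - 1), "p": float(res.pvalue)}


def t_ind(a: np.ndarray, b: np.ndarray) -> dict:
    """Two-tailed independent sample t-test (pooled variance)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df if df > 0 else 0.0
    if np.allclose(pooled, 0.0):
        raise ValueError("zero pooled variance; t undefined")
    res = sps.ttest_ind(a, b, equal_var=True)
    return {"t": float(res.statistic), "df": int(df), "p": float(res.pvalue)}


def t_ind_from_stats(mean1: float, std1: float, n1: int,
                     mean2: float, std2: float, n2: int) -> dict:
    """Pooled-variance two-sample t from group summary statistics."""
    res = sps.ttest_ind_from_stats(mean1, std1, n1, mean2, std2, n2, equal_var=True)
    return {"t": float(res.statistic), "df": int(n1 + n2 - 2), "p": float(res.pvalue)}


def cohens_d(t: float, n_or_df: int, design: str) -> float:
    """Cohen's d from a t statistic.

    dependent design: d = t / sqrt(N) with N the number of pairs;
    independent design: d = 2 t / sqrt(df).
    """
    if n_or_df <= 0:
        raise ValueError("n_or_df must be positive")
    if design == "dependent":
        return float(t) / float(np.sqrt(n_or_df))
    if design == "independent":
        return 2.0 * float(t) / float(np.sqrt(n_or_df))
    raise ValueError(f"unknown design {design!r}")
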