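"""Cross-run conditional Granger causality as a neural predictive-recall measure.

For every channel, the two listening runs provide a pair of amplitude series
x (run 1) and y (run 2); z is the stimulus audio envelope.  A trivariate
vector-autoregression of order p is fitted by ordinary least squares:

    x_t = sum_k A_xx,k x_{t-k} + sum_k A_xy,k y_{t-k} + sum_k A_xz,k z_{t-k} + e_t

and compared to the reduced model that omits the cross-run predictor y.  The
Granger statistic is the log-ratio of reduced to full residual variances,

    F_{y->x|z} = ln( sigma'_xx / sigma_xx ),

i.e. how much the past of the other run improves prediction of this run's
future over and above the run's own past and the stimulus.  Listening with
episodic memory makes information appear *earlier* in run 2, so the past of
run 2 predicts the future of run 1 but not vice versa: predictive recall is
the per-channel asymmetry delta_F = F_{2->1|z} - F_{1->2|z}.

Both directions come from the same order p, selected once per channel by
minimizing AIC over a fast Levinson-Whittle (LWR) recursion on the joint
trivariate process; the final models are always refitted by OLS.  No
small-sample bias correction is applied: the two directions share a model
order and sample count, so first-order bias cancels in the difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .stats import perm_pvalue

__all__ = [
    "VarModel",
    "GCResult",
    "select_order",
    "gc_pair",
    "cross_run_gc",
    "sign_flip_test",
    "select_cpr_channels",
    "effect_size_patientwise",
]


@dataclass
class VarModel:
    """Coefficient blocks and residual variances of one directed fit."""

    order: int
    a_own: np.ndarray  # A_xx,k — the target's own past
    a_cross: np.ndarray  # A_xy,k — the other run's past (the tested block)
    a_cond: np.ndarray  # A_xz,k — the conditioning envelope's past
    sigma_full: float
    sigma_reduced: float

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("model order must be >= 1")
        if self.sigma_full <= 0 or self.sigma_reduced <= 0:
            raise ValueError("residual variances must be positive")
        # OLS nesting can only be violated by numerical noise
        if self.sigma_reduced < self.sigma_full * (1 - 1e-10):
            raise ValueError("reduced-model variance below full-model variance")

    @property
    def f_value(self) -> float:
        return float(np.log(self.sigma_reduced / self.sigma_full))


@dataclass
class GCResult:
    """Both directed statistics for one channel."""

    channel: str
    f_21: float  # run2 -> run1 | envelope
    f_12: float  # run1 -> run2 | envelope
    order: int
    model_x: VarModel  # target = run 1
    model_y: VarModel  # target = run 2
    patient: str = ""

    @property
    def delta_f(self) -> float:
        return self.f_21 - self.f_12


def _sample_autocov(X: np.ndarray, p: int) -> np.ndarray:
    """Biased sample autocovariances R_0..R_p of a (d, n) series."""
    d, n = X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    R = np.empty((p + 1, d, d))
    for k in range(p + 1):
        R[k] = Xc[:, k:] @ Xc[:, : n - k].T / n
    return R


def _whittle_residuals(R: np.ndarray, p_max: int) -> np.ndarray:
    """Forward residual covariances at each order via the Whittle (LWR)
    multivariate Levinson recursion.  Returns (p_max, d, d); entry k-1 is the
    prediction-error covariance of the order-k model."""
    d = R.shape[1]
    sig_f = R[0].copy()
    sig_b = R[0].copy()
    A: list[np.ndarray] = []  # forward coefficients of the current order
    B: list[np.ndarray] = []  # backward coefficients
    out = np.empty((p_max, d, d))
    for k in range(1, p_max + 1):
        delta = R[k].copy()
        for i, Ai in enumerate(A, start=1):
            delta -= Ai @ R[k - i]
        K_f = np.linalg.solve(sig_b.T, delta.T).T  # delta @ sig_b^{-1}
        K_b = np.linalg.solve(sig_f.T, delta).T  # delta.T @ sig_f^{-1}
        A_new = [Ai - K_f @ B[k - 1 - i - 1] for i, Ai in enumerate(A)]
        B_new = [Bi - K_b @ A[k - 1 - i - 1] for i, Bi in enumerate(B)]
        A = A_new + [K_f]
        B = B_new + [K_b]
        sig_f = sig_f - K_f @ delta.T
        sig_b = sig_b - K_b @ delta
        out[k - 1] = sig_f
    return out


def select_order(x: np.ndarray, y: np.ndarray, z: np.ndarray, p_max: int = 50,
                 criterion: str = "AIC") -> int:
    """Model order (1..p_max) minimizing AIC of the joint trivariate process.

    The scan runs through the fast LWR recursion on sample autocovariances;
    the final model at the selected order is always refitted by OLS in
    :func:`gc_pair`.
    """
    if criterion != "AIC":
        raise ValueError("only the AIC criterion is implemented")
    X = np.vstack([np.asarray(s, dtype=float) for s in (x, y, z)])
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in input series")
    d, n = X.shape
    if n < 20 * p_max:
        raise ValueError(f"need >= 20*p_max samples ({20 * p_max}), got {n}")
    sig = _whittle_residuals(_sample_autocov(X, p_max), p_max)
    orders = np.arange(1, p_max + 1)
    _, logdets = np.linalg.slogdet(sig)
    aic = n * logdets + 2.0 * d * d * orders
    return int(orders[np.argmin(aic)])


def _lag_matrix(series: np.ndarray, p: int) -> np.ndarray:
    """Columns [s_{t-1}, ..., s_{t-p}] for t = p..n-1, shape (n-p, p)."""
    s = np.asarray(series, dtype=float)
    n = s.size
    return np.column_stack([s[p - k : n - k] for k in range(1, p + 1)])


def _ols_sigma(design: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    # minimum-norm lstsq tolerates duplicated predictor blocks (x == y is a
    # legitimate degenerate input with delta_F = 0); truly singular fits are
    # caught below via the residual variance
    coef, _, _, _ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coef
    sigma = float(resid @ resid / target.size)
    if not np.isfinite(sigma) or sigma <= 0.0:
        raise np.linalg.LinAlgError("degenerate design: zero residual variance")
    return coef, sigma


def _directed_fit(target: np.ndarray, own: np.ndarray, cross: np.ndarray,
                  cond: np.ndarray, p: int) -> VarModel:
    yt = target[p:]
    L_own, L_cross, L_cond = _lag_matrix(own, p), _lag_matrix(cross, p), _lag_matrix(cond, p)
    full = np.hstack([L_own, L_cross, L_cond])
    coef, sigma_full = _ols_sigma(full, yt)
    _, sigma_red = _ols_sigma(np.hstack([L_own, L_cond]), yt)
    return VarModel(
        order=p,
        a_own=coef[:p],
        a_cross=coef[p : 2 * p],
        a_cond=coef[2 * p :],
        sigma_full=sigma_full,
        sigma_reduced=sigma_red,
    )


def gc_pair(x: np.ndarray, y: np.ndarray, z: np.ndarray, p: int,
            channel: str = "", patient: str = "") -> GCResult:
    """Cross-run conditional GC for one channel, both directions.

    x is the run-1 series, y the run-2 series, z the audio envelope; all are
    demeaned before fitting.  Both directed models share the order p.
    """
    x = np.asarray(x, dtype=float) - np.mean(x)
    y = np.asarray(y, dtype=float) - np.mean(y)
    z = np.asarray(z, dtype=float) - np.mean(z)
    if not (x.size == y.size == z.size):
        raise ValueError("x, y, z must have equal length")
    try:
        model_x = _directed_fit(x, own=x, cross=y, cond=z, p=p)
        model_y = _directed_fit(y, own=y, cross=x, cond=z, p=p)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"channel {channel or '?'}: {err}") from err
    return GCResult(
        channel=channel,
        f_21=model_x.f_value,
        f_12=model_y.f_value,
        order=p,
        model_x=model_x,
        model_y=model_y,
        patient=patient,
    )


def cross_run_gc(run1, run2, envelope, p_max: int = 50, order: int | None = None,
                 shared_order: bool = True, channels: list[int] | None = None,
                 patient: str = "") -> tuple[pd.DataFrame, list[GCResult]]:
    """Per-channel cross-run GC over a pair of aligned recording runs.

    If ``order`` is given it is used everywhere; otherwise AIC selects it —
    once on the first analysed channel when ``shared_order`` (cheap), or per
    channel when not.
    """
    z = envelope.values
    idx = list(range(run1.n_channels)) if channels is None else list(channels)
    results: list[GCResult] = []
    p_shared: int | None = order
    for c in idx:
        x, y = run1.data[c], run2.data[c]
        if p_shared is None or (order is None and not shared_order):
            p_c = select_order(x, y, z, p_max=p_max)
            if shared_order and p_shared is None:
                p_shared = p_c
        if shared_order or order is not None:
            p_c = p_shared if order is None else order
        results.append(gc_pair(x, y, z, p_c, channel=run1.channel_labels[c], patient=patient))
    table = pd.DataFrame(
        {
            "channel": [r.channel for r in results],
            "patient": [r.patient for r in results],
            "F_21": [r.f_21 for r in results],
            "F_12": [r.f_12 for r in results],
            "delta_F": [r.delta_f for r in results],
            "order": [r.order for r in results],
        }
    )
    return table, results


def sign_flip_test(delta_f: np.ndarray, groups: np.ndarray | None = None,
                   n_perm: int = 1000, seed: int = 0) -> dict:
    """Random sign-flip test of the mean delta_F across channels.

    With ``groups`` (e.g. patient ids) the same flip applies to every channel
    of a group; when at most ~2^12 distinct flips exist they are enumerated
    exactly (9 patients -> 512 flips), otherwise flips are sampled.
    """
    d = np.asarray(delta_f, dtype=float)
    observed = float(d.mean())
    if groups is None:
        units = np.arange(d.size)
    else:
        groups = np.asarray(groups)
        _, units = np.unique(groups, return_inverse=True)
    n_units = int(units.max()) + 1
    if n_units < 2:
        raise ValueError("need >= 2 units to permute")
    group_sums = np.bincount(units, weights=d, minlength=n_units)
    if n_units <= 12:
        signs = np.array(list(product((1.0, -1.0), repeat=n_units)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(n_perm, n_units))
    null = signs @ group_sums / d.size
    return {
        "observed_mean": observed,
        "p": perm_pvalue(observed, null),
        "null": null,
        "n_perm": int(signs.shape[0]),
        "exact": n_units <= 12,
    }


def select_cpr_channels(delta_f: np.ndarray, posterior_ratio: float = 10.0,
                        seed: int = 0, n_init: int = 20,
                        max_restarts: int = 5) -> dict:
    """Cortical predictive-recall channel selection via a two-component
    Gaussian mixture on the delta_F distribution.

    The component with the lower mean is the null ("no learning")
    distribution; a channel is selected iff the posterior probability of the
    effect component is at least ``posterior_ratio`` times that of the null
    component.
    """
    d = np.asarray(delta_f, dtype=float)
    if d.size < 10:
        raise ValueError("need >= 10 channels to fit the mixture")
    if np.ptp(d) == 0:
        raise ValueError("degenerate input: all delta_F identical")
    X = d[:, None]
    last_err: Exception | None = None
    for attempt in range(max_restarts):
        try:
            gmm = GaussianMixture(
                n_components=2, n_init=n_init, random_state=seed + attempt,
                reg_covar=1e-10 * max(np.var(d), 1e-30),
            ).fit(X)
            if np.any(gmm.covariances_.ravel() <= 0):
                raise ValueError("zero-variance mixture component")
            break
        except (ValueError, np.linalg.LinAlgError) as err:  # pragma: no cover
            last_err = err
    else:  # pragma: no cover
        raise RuntimeError(f"mixture fit failed after {max_restarts} restarts: {last_err}")
    means = gmm.means_.ravel()
    effect = int(np.argmax(means))
    post = gmm.predict_proba(X)
    with np.errstate(divide="ignore"):
        ratio = post[:, effect] / np.maximum(post[:, 1 - effect], 1e-300)
    selected = np.flatnonzero(ratio >= posterior_ratio)
    return {
        "selected": selected,
        "posterior_ratio": ratio,
        "means": means,
        "variances": gmm.covariances_.ravel(),
        "weights": gmm.weights_.ravel(),
        "effect_component": effect,
    }


def effect_size_patientwise(delta_f: np.ndarray, patient_ids: np.ndarray) -> float:
    """d = mean of per-patient mean delta_F divided by their SD (ddof=1)."""
    d = np.asarray(delta_f, dtype=float)
    ids = np.asarray(patient_ids)
    uniq, inv = np.unique(ids, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("need >= 2 patients")
    means = np.bincount(inv, weights=d) / np.bincount(inv)
    sd = means.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of patient means: d undefined")
    return float(means.mean() / sd)
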