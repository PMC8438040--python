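"""Synthetic-data generator for the whole pipeline.

Emulates every input the analyses consume, with known ground truth:

* segmentation press logs for two listening runs, where run-2 responses are
  advanced by a controllable amount (the behavioral signature of anticipating
  event boundaries);
* per-word prediction tables with a learning increment between a naive and a
  previously-exposed group;
* two-run multichannel 100 Hz band-amplitude recordings that share a smooth
  stimulus-driven latent.  On a designated subset of "effect" channels the
  run-2 copy of the latent is time-advanced, which is exactly the structure
  the cross-run Granger analysis detects.  Designated "hippocampal" channels
  carry a lag-shifted copy of the shared latent inside configurable coupling
  windows, the structure the lagged mutual-information analysis detects.

The shared latent is low-pass-filtered Gaussian noise (8 Hz cutoff at the
100 Hz analysis rate) scaled to unit variance; time advances are realized as
integer-sample shifts with the wrapped edge discarded, so planted lags are
exact.  All randomness flows from one seeded generator per call; sub-streams
are spawned deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sig

from .behavior import PressLog, make_word_table
from .preprocess import ANALYSIS_RATE, AudioEnvelope, RecordingRun

__all__ = [
    "SimulationTruth",
    "gen_segmentation_logs",
    "gen_word_table",
    "gen_two_run_recording",
]


@dataclass
class SimulationTruth:
    """Ground truth of one simulated two-run experiment."""

    anticipation_shift_ms: np.ndarray  # per channel; > 0 only on effect channels
    effect_channels: np.ndarray  # indices into the cortical channels
    boundary_times_ms: np.ndarray
    coupling_lag_ms: float  # signed; negative = hippocampus leads cortex
    coupling_windows: list[tuple[float, float]]  # ms intervals where coupling is on
    word_learning_delta: np.ndarray | float = 0.0
    seed: int = 0
    coupling_runs: tuple[int, ...] = (1, 2)
    coupling_strength: float = 1.0

    def __post_init__(self) -> None:
        self.anticipation_shift_ms = np.asarray(self.anticipation_shift_ms, dtype=float)
        self.effect_channels = np.asarray(self.effect_channels, dtype=int)
        self.boundary_times_ms = np.asarray(self.boundary_times_ms, dtype=float)
        if np.any(self.anticipation_shift_ms < 0):
            raise ValueError("anticipation_shift_ms must be nonnegative")
        mask = np.zeros(self.anticipation_shift_ms.size, dtype=bool)
        mask[self.effect_channels] = True
        if np.any(self.anticipation_shift_ms[~mask] != 0):
            raise ValueError("anticipation_shift_ms must be zero off the effect channels")
        if self.boundary_times_ms.size > 1 and np.any(np.diff(self.boundary_times_ms) <= 0):
            raise ValueError("boundary_times_ms must be strictly increasing")


def gen_segmentation_logs(n_participants: int, boundary_times: np.ndarray,
                          story_duration_ms: float, advance_ms: float = 0.0,
                          response_jitter_sd: float = 300.0, hit_prob: float = 0.9,
                          false_press_rate: float = 0.5, seed: int = 0,
                          response_jitter_sd_run2: float | None = None,
                          ) -> tuple[list[PressLog], list[PressLog]]:
    """Two runs of synthetic segmentation press logs.

    Run-1 presses sit at boundary + Gaussian jitter; run-2 presses are
    additionally advanced by ``advance_ms`` (anticipation) and may use their
    own jitter SD (tighter run-2 responses model increased consensus after
    one exposure).  False presses arrive as a Poisson process at
    ``false_press_rate`` per minute.
    """
    if response_jitter_sd_run2 is None:
        response_jitter_sd_run2 = response_jitter_sd
    if not 0.0 <= hit_prob <= 1.0:
        raise ValueError("hit_prob must lie in [0, 1]")
    if min(advance_ms, response_jitter_sd, response_jitter_sd_run2, false_press_rate) < 0:
        raise ValueError("durations and rates must be nonnegative")
    boundary_times = np.asarray(boundary_times, dtype=float)
    if boundary_times.size and (boundary_times.min() < 0 or boundary_times.max() > story_duration_ms):
        raise ValueError("boundary times must lie inside the story")
    rng = np.random.default_rng(seed)
    runs: tuple[list[PressLog], list[PressLog]] = ([], [])
    jitters = (response_jitter_sd, response_jitter_sd_run2)
    for i in range(n_participants):
        for run_idx, shift in ((0, 0.0), (1, advance_ms)):
            hits = boundary_times[rng.random(boundary_times.size) < hit_prob]
            presses = hits - shift
            if jitters[run_idx] > 0:
                presses = presses + rng.normal(0.0, jitters[run_idx], size=presses.size)
            n_false = rng.poisson(false_press_rate * story_duration_ms / 60000.0)
            presses = np.concatenate([presses, rng.uniform(0, story_duration_ms, n_false)])
            presses = presses[(presses >= 0) & (presses <= story_duration_ms)]
            runs[run_idx].append(
                PressLog(f"p{i:03d}", run_idx + 1, np.sort(presses), int(story_duration_ms))
            )
    return runs


def _draw(spec, rng: np.random.Generator, n: int) -> np.ndarray:
    """A distribution spec is either a scalar or a callable(rng, n) -> array."""
    if callable(spec):
        return np.asarray(spec(rng, n), dtype=float)
    return np.full(n, float(spec))


def gen_word_table(n_words: int, base_prob_fn=0.2, delta_fn=0.2,
                   word_duration_ms: float = 350.0, gap_ms: float = 120.0,
                   n_per_group: int = 50, seed: int = 0,
                   ) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Per-word prediction table plus per-participant correctness matrices.

    The exposed group's per-word probability is naive + delta (clipped to
    [0, 1]); correctness matrices are Bernoulli draws at those probabilities,
    one row per participant of each group.
    """
    if n_words < 2:
        raise ValueError("need at least two words")
    rng = np.random.default_rng(seed)
    p_naive = np.clip(_draw(base_prob_fn, rng, n_words), 0.0, 1.0)
    delta = _draw(delta_fn, rng, n_words)
    p_exposed = np.clip(p_naive + delta, 0.0, 1.0)
    onsets = np.arange(n_words) * (word_duration_ms + gap_ms)
    table = make_word_table(
        pd.DataFrame(
            {
                "token": [f"w{i:04d}" for i in range(n_words)],
                "onset_ms": onsets,
                "offset_ms": onsets + word_duration_ms,
                "p_naive": p_naive,
                "p_exposed": p_exposed,
            }
        )
    )
    matrices = {
        "naive": (rng.random((n_per_group, n_words)) < p_naive).astype(np.uint8),
        "exposed": (rng.random((n_per_group, n_words)) < p_exposed).astype(np.uint8),
    }
    return table, matrices


def _lowpass_noise(rng: np.random.Generator, n: int, fs: float, cutoff: float = 8.0) -> np.ndarray:
    sos = sig.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")
    x = sig.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _ar2_noise(rng: np.random.Generator, shape: tuple[int, ...],
               a1: float = 0.5, a2: float = -0.2) -> np.ndarray:
    e = rng.standard_normal(shape)
    x = sig.lfilter([1.0], [1.0, -a1, -a2], e, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def gen_two_run_recording(n_channels: int, n_hippo: int, duration_s: float,
                          truth: SimulationTruth, fs: float = ANALYSIS_RATE,
                          snr: float = 1.0, outlier_rate_per_min: float = 0.0,
                          ) -> tuple[RecordingRun, RecordingRun, AudioEnvelope, SimulationTruth]:
    """Two-run multichannel amplitude recording with planted structure.

    Cortical channel c of run r is ``snr * latent(+shift) + AR(2) noise``;
    the latent is shared across channels and runs, advanced by the channel's
    ``anticipation_shift_ms`` in run 2 only.  Hippocampal channels (appended
    after the cortical ones, labels ``hippo*``) carry a copy of the latent
    shifted by ``coupling_lag_ms`` inside the coupling windows of the runs
    named in ``truth.coupling_runs``.  The envelope shares part of the
    latent's variance, mimicking stimulus-driven cortical entrainment.
    """
    if duration_s < 60:
        raise ValueError("need >= 60 s for stable VAR fits")
    if fs != ANALYSIS_RATE:
        warnings.warn(
            f"requested fs={fs} Hz differs from the analysis rate; "
            f"generating at {ANALYSIS_RATE} Hz", stacklevel=2,
        )
        fs = ANALYSIS_RATE
    if truth.anticipation_shift_ms.size != n_channels:
        raise ValueError("truth.anticipation_shift_ms must have one entry per cortical channel")
    n = int(round(duration_s * fs))
    shifts = np.round(truth.anticipation_shift_ms * fs / 1000.0).astype(int)
    max_shift = int(shifts.max()) if shifts.size else 0
    lag_samp = int(round(truth.coupling_lag_ms * fs / 1000.0))
    margin = max_shift + abs(lag_samp) + 1

    rng = np.random.default_rng(truth.seed)
    r_lat, r_env, r_noise, r_hip, r_out = rng.spawn(5)

    # stimulus-driven component (drives the envelope) + story component; both
    # appear in cortex, only the first is visible to the conditioning series.
    ext = n + 2 * margin
    env_comp = _lowpass_noise(r_env, ext, fs)
    story_comp = _lowpass_noise(r_lat, ext, fs)
    latent = np.sqrt(0.5) * env_comp + np.sqrt(0.5) * story_comp
    envelope = np.log1p(np.exp(env_comp[margin : margin + n]))  # softplus, nonneg

    lat1 = latent[margin : margin + n]
    noise = _ar2_noise(r_noise, (2, n_channels + n_hippo, n))
    data1 = snr * lat1[None, :] + noise[0, :n_channels]
    data2 = np.empty_like(data1)
    for c in range(n_channels):
        # run-2 advance: the channel carries the latent `shift` samples early
        data2[c] = snr * latent[margin + shifts[c] : margin + shifts[c] + n] + noise[1, c]

    hippo1 = noise[0, n_channels:].copy()
    hippo2 = noise[1, n_channels:].copy()
    if n_hippo and truth.coupling_windows:
        # coupling windows designate *cortical* event times; the hippocampal
        # copy of the latent is active lag samples later (earlier for a lead),
        # so that h[t] = latent[t - lag] exactly when t - lag is in a window
        win_mask = np.zeros(n, dtype=bool)
        for lo, hi in truth.coupling_windows:
            win_mask[int(lo * fs / 1000.0) : int(hi * fs / 1000.0)] = True
        tt = np.arange(n)
        src = tt - lag_samp
        valid = (src >= 0) & (src < n)
        hippo_mask = np.zeros(n, dtype=bool)
        hippo_mask[tt[valid]] = win_mask[src[valid]]
        # the lag is defined relative to the run's *cortical* signal: in run 2
        # the effect channels carry the advanced latent, so the coupled copy
        # advances with them
        eff_shift = {1: 0, 2: int(np.round(shifts[truth.effect_channels].mean()))
                     if truth.effect_channels.size else 0}
        for arr, run_id in ((hippo1, 1), (hippo2, 2)):
            if run_id in truth.coupling_runs:
                start = margin + eff_shift[run_id] - lag_samp
                coupled = truth.coupling_strength * latent[start : start + n]
                arr[:, hippo_mask] += coupled[hippo_mask]

    full1 = np.vstack([data1, hippo1])
    full2 = np.vstack([data2, hippo2])
    if outlier_rate_per_min > 0:
        for arr in (full1, full2):
            n_out = r_out.poisson(outlier_rate_per_min * duration_s / 60.0, size=arr.shape[0])
            for ch, k in enumerate(n_out):
                pos = r_out.integers(0, n, size=k)
                iqr = np.subtract(*np.percentile(arr[ch], [75, 25]))
                arr[ch, pos] += 20.0 * max(iqr, 1e-12)
    labels = [f"ch{c:03d}" for c in range(n_channels)] + [f"hippo{h:02d}" for h in range(n_hippo)]
    run1 = RecordingRun(full1, fs, labels, 1)
    run2 = RecordingRun(full2, fs, labels, 2)
    return run1, run2, AudioEnvelope(envelope, fs), truth
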