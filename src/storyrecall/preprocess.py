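"""Signal conditioning for the neural analyses.

Converts multichannel recordings into the representations the downstream
models consume: band-limited Hilbert amplitudes, the 100 Hz analysis rate,
outlier-cleaned aligned two-run matrices, and the 7-row per-channel feature
stack (raw signal plus six canonical band amplitudes) used by the
connectivity analysis.

All filters are zero-phase 4th-order Butterworth designs applied
forward-backward (so the effective attenuation is doubled); the Hilbert
envelope is computed on a reflection-padded copy of the signal (1 s padding)
to suppress edge artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sig
from scipy.interpolate import PchipInterpolator

__all__ = [
    "RecordingRun",
    "AudioEnvelope",
    "ANALYSIS_RATE",
    "BANDS",
    "band_amplitude",
    "to_analysis_rate",
    "clean_and_align",
    "interpolate_outliers",
    "feature_stack",
]

ANALYSIS_RATE = 100.0  # Hz; common rate of all downstream analyses

# Canonical frequency bands: name -> (low, high) Hz.  A low edge of 0 means a
# lowpass band.  Row order of the feature stack is fixed: raw, then these.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 15.0),
    "beta": (15.0, 30.0),
    "low_gamma": (35.0, 55.0),
    "high_gamma": (70.0, 200.0),
}


@dataclass
class RecordingRun:
    """channels x samples amplitude matrix for one listening run."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    run: int

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.run not in (1, 2):
            raise ValueError("run must be 1 or 2")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class AudioEnvelope:
    """Amplitude envelope of the story audio (the conditioning series Z)."""

    values: np.ndarray
    fs: float = ANALYSIS_RATE
    band: tuple[float, float] = (200.0, 5000.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if np.any(self.values < 0):
            raise ValueError("envelope values must be nonnegative")


def _butter_sos(fs: float, band: tuple[float, float]):
    low, high = band
    nyq = fs / 2.0
    if high >= nyq:
        raise ValueError(f"band edge {high} Hz at or above Nyquist ({nyq} Hz)")
    if low <= 0:
        return sig.butter(4, high, btype="lowpass", fs=fs, output="sos")
    return sig.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def band_amplitude(signal: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Band-limited amplitude: zero-phase Butterworth bandpass followed by the
    magnitude of the analytic (Hilbert) signal."""
    x = np.asarray(signal, dtype=float)
    sos = _butter_sos(fs, band)
    filt = sig.sosfiltfilt(sos, x, axis=-1)
    pad = min(int(round(fs)), x.shape[-1] - 1)  # 1 s reflection padding
    padded = np.concatenate(
        [filt[..., pad:0:-1], filt, filt[..., -2 : -pad - 2 : -1]], axis=-1
    )
    analytic = sig.hilbert(padded, axis=-1)
    return np.abs(analytic)[..., pad : pad + x.shape[-1]]


def to_analysis_rate(series: np.ndarray, fs: float, fs_out: float = ANALYSIS_RATE) -> np.ndarray:
    """Anti-alias filtered resampling to the analysis rate."""
    x = np.asarray(series, dtype=float)
    if fs < fs_out:
        raise ValueError("cannot upsample: fs below the analysis rate")
    if fs == fs_out:
        return x.copy()
    frac = Fraction(fs_out / fs).limit_denominator(10000)
    y = sig.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    n_target = int(round(x.shape[-1] * fs_out / fs))
    if y.shape[-1] > n_target:
        y = y[..., :n_target]
    elif y.shape[-1] < n_target:  # pragma: no cover - resample_poly rounds up
        y = np.pad(y, [(0, 0)] * (y.ndim - 1) + [(0, n_target - y.shape[-1])], mode="edge")
    return y


def interpolate_outliers(x: np.ndarray, n_iqr: float = 5.0, pad: int = 5) -> np.ndarray:
    """Replace amplitude outliers by monotone piecewise-cubic interpolation.

    Samples strictly exceeding median + ``n_iqr`` * IQR (per channel, over the
    full run) are replaced together with ``pad`` samples on each side; gaps at
    the edges are filled with the nearest valid value.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    out = x.copy()
    n = x.shape[1]
    idx = np.arange(n)
    for ch in range(x.shape[0]):
        row = x[ch]
        q1, med, q3 = np.percentile(row, [25, 50, 75])
        thr = med + n_iqr * (q3 - q1)
        bad = row > thr
        if not bad.any():
            continue
        # dilate the outlier mask by +-pad samples
        kernel = np.ones(2 * pad + 1, dtype=bool)
        bad = np.convolve(bad, kernel, mode="same") > 0
        good = ~bad
        if good.sum() < 2:
            raise ValueError(f"channel {ch}: too few clean samples to interpolate")
        interp = PchipInterpolator(idx[good], row[good], extrapolate=False)
        filled = interp(idx[bad])
        # edge gaps: hold the nearest valid sample
        nan = np.isnan(filled)
        if nan.any():
            first_good, last_good = idx[good][0], idx[good][-1]
            bad_idx = idx[bad]
            filled[nan & (bad_idx < first_good)] = row[first_good]
            filled[nan & (bad_idx > last_good)] = row[last_good]
        out[ch, bad] = filled
    return out if x.shape[0] > 1 else out


def clean_and_align(run1: RecordingRun, run2: RecordingRun,
                    envelope: AudioEnvelope,
                    n_iqr: float = 5.0, pad: int = 5,
                    ) -> tuple[RecordingRun, RecordingRun, AudioEnvelope]:
    """Common-length truncation, per-channel linear detrend, and 5-IQR outlier
    interpolation of both runs; the envelope is truncated alongside."""
    if not (run1.fs == run2.fs == envelope.fs):
        raise ValueError("runs and envelope must share a sampling rate")
    fs = run1.fs
    n = min(run1.n_samples, run2.n_samples, envelope.values.size)
    if n < 10 * fs:
        raise ValueError("runs shorter than 10 s cannot be analysed")
    cleaned = []
    for run in (run1, run2):
        data = sig.detrend(run.data[:, :n], axis=1, type="linear")
        data = interpolate_outliers(data, n_iqr=n_iqr, pad=pad)
        cleaned.append(RecordingRun(data, fs, list(run.channel_labels), run.run))
    env = AudioEnvelope(envelope.values[:n], fs, envelope.band)
    return cleaned[0], cleaned[1], env


def feature_stack(raw_channel: np.ndarray, fs: float,
                  fs_out: float = ANALYSIS_RATE) -> np.ndarray:
    """7-row feature stack of one channel at the analysis rate.

    Row 0 is the (resampled) raw signal; rows 1-6 are the band amplitudes in
    the fixed order delta, theta, alpha, beta, low gamma, high gamma.  Bands
    are computed at the native rate before downsampling, so the stack is
    complete whenever the native rate supports every band (>= 400 Hz for the
    high-gamma band).  A band whose upper edge reaches the native Nyquist is
    clipped just below it with a warning.
    """
    x = np.asarray(raw_channel, dtype=float).ravel()
    rows = [to_analysis_rate(x, fs, fs_out)]
    nyq = fs / 2.0
    for name, (low, high) in BANDS.items():
        if low >= nyq:
            raise ValueError(
                f"band {name} ({low}-{high} Hz) infeasible at fs={fs} Hz; "
                "compute the stack on the signal before downsampling"
            )
        if high >= nyq:
            warnings.warn(
                f"band {name} upper edge clipped to Nyquist at fs={fs} Hz",
                stacklevel=2,
            )
            high = 0.95 * nyq
        amp = band_amplitude(x, fs, (low, high))
        rows.append(to_analysis_rate(amp, fs, fs_out))
    return np.vstack(rows)
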