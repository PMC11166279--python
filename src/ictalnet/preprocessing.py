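"""Labeling rules, 30-second windowing, optional ICA denoising, and STFT features.

The labeling conventions follow the cross-patient protocol used with the
CHB-MIT corpus:

* seizures separated by less than 30 minutes are merged into one event;
* interictal time must lie at least 4 hours away from any seizure (the
  buffer is a parameter — fixture-scale tests shrink it);
* each labeled segment is tiled into consecutive, non-overlapping 30 s
  windows, dropping any trailing remainder;
* each window is turned into a per-channel magnitude spectrogram with a
  Gaussian-window short-time Fourier transform.

The STFT defaults (256-sample Gaussian window with sigma = 32 samples, hop
128, one-sided, log(1+|.|) compression) give 1 Hz resolution over the 0-128
Hz band; a ``freq_crop_hz`` option restricts the feature to the 0-40 Hz band
where ictal energy concentrates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal.windows import gaussian as gaussian_window
from scipy.stats import kurtosis
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .eeg_io import EEGRecord, Interval, SeizureAnnotation

logger = logging.getLogger(__name__)


@dataclass
class LabeledWindow:
    """One 30 s multichannel segment with its ictal (1) / interictal (0) label."""
    patient_id: str
    start_s: float
    samples: np.ndarray  # channels x (window_s * fs)
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        self.samples = np.asarray(self.samples, dtype=np.float64)


@dataclass
class StftConfig:
    window_len: int = 256
    hop: int = 128
    sigma: float | None = None  # Gaussian std in samples; None -> window_len / 8
    one_sided: bool = True
    log_magnitude: bool = True
    freq_crop_hz: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.hop <= self.window_len:
            raise ValueError(f"need 0 < hop <= window_len, got hop={self.hop}")
        if self.sigma is None:
            self.sigma = self.window_len / 8.0
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def window(self) -> np.ndarray:
        return gaussian_window(self.window_len, std=self.sigma, sym=True)


@dataclass
class Spectrogram:
    """channels x freq_bins x time_frames non-negative magnitude feature."""
    values: np.ndarray
    freq_resolution_hz: float
    hop_s: float
    freqs_hz: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrogram contains non-finite values")


# -- interval algebra ------------------------------------------------------

def merge_seizure_intervals(intervals: Sequence[Interval],
                            gap_s: float = 1800.0) -> list[Interval]:
    """Union consecutive seizures whose gap is below ``gap_s`` (30 min default).

    Merging is transitive: a chain of events each under the gap collapses to
    one.  Overlapping input intervals are unioned as well.
    """
    if gap_s < 0:
        raise ValueError("gap_s must be non-negative")
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    for a, b in ivs:
        if b <= a:
            raise ValueError(f"invalid interval ({a}, {b})")
    merged: list[Interval] = []
    for a, b in ivs:
        if merged and a - merged[-1][1] < gap_s:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def label_segments(merged: SeizureAnnotation | Sequence[Interval],
                   record_span_s: float,
                   buffer_s: float = 14400.0) -> tuple[list[Interval], list[Interval]]:
    """Split [0, T] into ictal and interictal segments.

    Ictal segments are the merged seizures themselves; interictal time is the
    complement of every seizure dilated by ``buffer_s`` (4 h by default) on
    both sides.  Time inside the buffer but outside a seizure belongs to
    neither class and yields no windows.
    """
    if buffer_s < 0:
        raise ValueError("buffer_s must be non-negative")
    T = float(record_span_s)
    ictal = [(max(0.0, a), min(T, b)) for a, b in merged]
    ictal = [(a, b) for a, b in ictal if b > a]
    # complement of the union of dilated intervals
    excluded = merge_seizure_intervals(
        [(max(0.0, a - buffer_s), min(T, b + buffer_s)) for a, b in merged
         if min(T, b + buffer_s) > max(0.0, a - buffer_s)],
        gap_s=0.0) if len(list(merged)) else []
    interictal: list[Interval] = []
    cursor = 0.0
    for a, b in excluded:
        if a > cursor:
            interictal.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < T:
        interictal.append((cursor, T))
    return ictal, interictal


def extract_windows(record: EEGRecord, intervals: Sequence[Interval],
                    label: int, window_s: float = 30.0) -> list[LabeledWindow]:
    """Tile each interval with consecutive non-overlapping ``window_s`` windows.

    Windows start at the interval start; a trailing remainder shorter than
    one window is dropped.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    n_per = int(round(window_s * record.fs))
    out: list[LabeledWindow] = []
    for a, b in intervals:
        k = int(np.floor((b - a) / window_s))
        for i in range(k):
            start = a + i * window_s
            s0 = int(round((start - record.start_time_s) * record.fs))
            out.append(LabeledWindow(patient_id=record.patient_id, start_s=start,
                                     samples=record.samples[:, s0:s0 + n_per],
                                     label=label))
    return out


# -- ICA denoising ---------------------------------------------------------

def ica_denoise(windows: list[LabeledWindow], kurtosis_threshold: float = 5.0,
                seed: int = 0, max_iter: int = 500) -> list[LabeledWindow]:
    """Reject heavy-tailed independent components, window by window.

    Each window is decomposed into as many independent components as channels
    (FastICA); components whose excess kurtosis exceeds the threshold in
    magnitude — the signature of spike-like artifacts rather than ongoing
    rhythms — are zeroed before reconstruction.  A window whose decomposition
    does not converge is passed through unchanged with a logged warning.
    """
    out: list[LabeledWindow] = []
    for idx, w in enumerate(windows):
        if w.samples.shape[0] < 2:
            raise ValueError("ICA requires at least 2 channels")
        ica = FastICA(n_components=w.samples.shape[0], whiten="unit-variance",
                      random_state=np.random.default_rng([seed, idx]).integers(2 ** 31),
                      max_iter=max_iter)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            sources = ica.fit_transform(w.samples.T)  # samples x components
        if any(issubclass(c.category, ConvergenceWarning) for c in caught):
            logger.warning("ICA did not converge on window %s@%ss; passing through",
                           w.patient_id, w.start_s)
            out.append(w)
            continue
        k = kurtosis(sources, axis=0, fisher=True)
        sources[:, np.abs(k) > kurtosis_threshold] = 0.0
        cleaned = ica.inverse_transform(sources).T
        out.append(LabeledWindow(w.patient_id, w.start_s, cleaned, w.label))
    return out


# -- STFT ------------------------------------------------------------------

def stft_features(window: LabeledWindow | np.ndarray, fs: float,
                  cfg: StftConfig | None = None) -> Spectrogram:
    """Gaussian-window short-time Fourier magnitude per channel.

    Frame m of channel c is ``|sum_n x[c, m*hop + n] w[n] exp(-2 pi i f n / L)|``
    over the window length L, i.e. the magnitude of the windowed DFT at hop
    steps with no padding; the number of frames is
    ``floor((n_samples - L) / hop) + 1``.  With ``log_magnitude`` the values
    are compressed as log(1 + |.|).
    """
    cfg = cfg or StftConfig()
    x = window.samples if isinstance(window, LabeledWindow) else np.asarray(window, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    n = x.shape[1]
    L, hop = cfg.window_len, cfg.hop
    if L > n:
        raise ValueError(f"window_len {L} exceeds signal length {n}")
    w = cfg.window()
    frames = np.lib.stride_tricks.sliding_window_view(x, L, axis=1)[:, ::hop, :]
    tapered = frames * w[None, None, :]
    if cfg.one_sided:
        spec = np.fft.rfft(tapered, axis=-1)
        freqs = np.fft.rfftfreq(L, d=1.0 / fs)
    else:
        spec = np.fft.fft(tapered, axis=-1)
        freqs = np.fft.fftfreq(L, d=1.0 / fs)
    mag = np.abs(spec).transpose(0, 2, 1)  # channels x freq x time
    if cfg.freq_crop_hz is not None:
        lo, hi = cfg.freq_crop_hz
        keep = (freqs >= lo) & (freqs <= hi)
        mag = mag[:, keep, :]
        freqs = freqs[keep]
    if cfg.log_magnitude:
        mag = np.log1p(mag)
    return Spectrogram(values=mag, freq_resolution_hz=fs / L, hop_s=hop / fs,
                       freqs_hz=freqs)


def fit_channel_norm(features: np.ndarray, eps: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/std over a (N, C, F, T) training stack.

    Computed on the training set only and applied to both splits, the
    standard stabilisation before the network input.
    """
    mean = features.mean(axis=(0, 2, 3), keepdims=True)
    std = features.std(axis=(0, 2, 3), keepdims=True) + eps
    return mean, std


def apply_channel_norm(features: np.ndarray, mean: np.ndarray,
                       std: np.ndarray) -> np.ndarray:
    return (features - mean) / std


def record_to_windows(record: EEGRecord, annotation: SeizureAnnotation,
                      merge_gap_s: float = 1800.0, buffer_s: float = 14400.0,
                      window_s: float = 30.0) -> list[LabeledWindow]:
    """Full labeling chain for one record: merge -> label -> tile."""
    merged = merge_seizure_intervals(list(annotation), gap_s=merge_gap_s)
    ictal, interictal = label_segments(merged, record.duration_s, buffer_s=buffer_s)
    windows = extract_windows(record, ictal, label=1, window_s=window_s)
    windows += extract_windows(record, interictal, label=0, window_s=window_s)
    return windows
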