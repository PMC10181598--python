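"""Windowed feature extraction from the preprocessed (level-4 detail) channels.

Both channels' detail series are cut into non-overlapping windows of four
coefficients; nine metrics are computed per channel per window, giving an
18-dimensional feature vector.  The default 32,500-sample session yields a
2032-coefficient level-4 series and hence 508 windows.

Per-channel metrics (population conventions, divide-by-n):

======== ==========================================================
RMS      sqrt(mean of squares)
AMP      peak-to-peak amplitude, max - min
Variance mean squared deviation from the window mean
Average  arithmetic mean
Median   middle value (mean of the middle pair for even width)
Cov      population covariance with the *other* channel's window
Max      maximum value
Pspect   maximum of the window's periodogram |FFT|^2 / width
Power    sum of absolute squares divided by the width (= RMS^2)
======== ==========================================================

The cross-channel covariance is symmetric, so CovarianceH == CovarianceV
for every window pair.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EOGRecording, N_CLASSES
from .wavelets import DEFAULT_MOTHER, WaveletSpec, decompose, smoothed_detail

__all__ = [
    "FEATURE_NAMES",
    "FeatureMatrix",
    "make_windows",
    "window_features",
    "build_feature_matrix",
]

_PER_CHANNEL = ("RMS", "AMP", "Variance", "Average", "Median", "Covariance", "Max", "Pspectrum", "Power")
FEATURE_NAMES: tuple[str, ...] = tuple(f"{m}H" for m in _PER_CHANNEL) + tuple(
    f"{m}V" for m in _PER_CHANNEL
)


def make_windows(series: np.ndarray, width: int = 4) -> np.ndarray:
    """Cut a series into consecutive non-overlapping windows, shape (n, width).

    A trailing remainder shorter than ``width`` is discarded.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size == 0:
        raise ValueError("series must be a non-empty one-dimensional array")
    if width < 1:
        raise ValueError("window width must be >= 1")
    n = series.size // width
    return series[: n * width].reshape(n, width)


def _periodogram_peak(windows: np.ndarray, reducer: str) -> np.ndarray:
    power = np.abs(np.fft.rfft(windows, axis=1)) ** 2 / windows.shape[1]
    if reducer == "max":
        return power.max(axis=1)
    if reducer == "sum":
        return power.sum(axis=1)
    raise ValueError(f"unknown Pspectrum reducer {reducer!r}; expected 'max' or 'sum'")


def _channel_features(own: np.ndarray, other: np.ndarray, reducer: str) -> np.ndarray:
    """Nine metrics per window for one channel; shape (n_windows, 9)."""
    mean = own.mean(axis=1)
    power = np.mean(own**2, axis=1)
    cov = np.mean(
        (own - mean[:, None]) * (other - other.mean(axis=1)[:, None]), axis=1
    )
    cols = [
        np.sqrt(power),                 # RMS
        own.max(axis=1) - own.min(axis=1),  # AMP
        power - mean**2,                # population variance
        mean,                           # Average
        np.median(own, axis=1),         # Median
        cov,                            # cross-channel covariance
        own.max(axis=1),                # Max
        _periodogram_peak(own, reducer),  # Pspectrum
        power,                          # Power
    ]
    return np.column_stack(cols)


def window_features(
    h_window: np.ndarray,
    v_window: np.ndarray,
    pspectrum_reducer: str = "max",
) -> np.ndarray:
    """The 18-dimensional feature vector of one window pair."""
    h = np.asarray(h_window, dtype=float)
    v = np.asarray(v_window, dtype=float)
    if h.shape != v.shape:
        raise ValueError("horizontal and vertical windows must have equal width")
    if h.ndim != 1 or h.size < 2:
        raise ValueError("windows must be 1-D with width >= 2")
    row_h = _channel_features(h[None, :], v[None, :], pspectrum_reducer)
    row_v = _channel_features(v[None, :], h[None, :], pspectrum_reducer)
    return np.concatenate([row_h[0], row_v[0]])


@dataclass
class FeatureMatrix:
    """Labelled windowed feature vectors; rows align with ``window_labels``."""

    X: np.ndarray
    window_labels: np.ndarray
    window_width: int = 4
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.window_labels = np.asarray(self.window_labels, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.window_labels.size:
            raise ValueError("feature rows and window labels must align")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} feature columns, got {self.X.shape[1]}"
            )

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=list(self.feature_names))
        frame["label"] = self.window_labels
        return frame

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "FeatureMatrix":
        frame = pd.read_csv(path)
        if "label" not in frame.columns:
            raise ValueError("feature CSV must contain a 'label' column")
        labels = frame.pop("label").to_numpy(dtype=int)
        return cls(
            frame.to_numpy(dtype=float),
            labels,
            feature_names=tuple(frame.columns),
        )

    def subset(self, index: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.X[index],
            self.window_labels[index],
            self.window_width,
            self.feature_names,
        )


def _majority_window_labels(
    labels: np.ndarray, n_windows: int, receptive_field: int
) -> np.ndarray:
    """Label of each window = majority class over the original samples it
    spans (ties break toward the lower class id)."""
    out = np.empty(n_windows, dtype=int)
    for w in range(n_windows):
        block = labels[w * receptive_field : (w + 1) * receptive_field]
        out[w] = np.bincount(block, minlength=N_CLASSES).argmax()
    return out


def build_feature_matrix(
    recording: EOGRecording,
    mother: WaveletSpec = DEFAULT_MOTHER,
    level: int = 4,
    width: int = 4,
    pspectrum_reducer: str = "max",
) -> FeatureMatrix:
    """Full preprocessing + feature stage: decompose both channels, take the
    level-``level`` details, window them in lockstep, and attach majority
    labels over each window's receptive field of ``width * 2**level``
    original samples."""
    if recording.labels is None:
        raise ValueError("build_feature_matrix requires a labelled recording")
    if width < 2:
        raise ValueError("window width must be >= 2 for variance and covariance")
    levels = max(level, 5)
    dh = smoothed_detail(decompose(recording.horizontal, mother, levels), level)
    dv = smoothed_detail(decompose(recording.vertical, mother, levels), level)
    wh = make_windows(dh, width)
    wv = make_windows(dv, width)
    X = np.hstack(
        [
            _channel_features(wh, wv, pspectrum_reducer),
            _channel_features(wv, wh, pspectrum_reducer),
        ]
    )
    labels = _majority_window_labels(
        recording.labels, wh.shape[0], width * 2**level
    )
    return FeatureMatrix(X, labels, window_width=width)
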