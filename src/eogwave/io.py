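"""Recording data model and readers/writers for labelled two-channel EOG.

An electrooculogram is recorded on two bipolar electrode pairs: a horizontal
channel (left/right gaze) and a vertical channel (up/down gaze and blinks).
The eyeball acts as a rotating corneo-retinal dipole, so each gaze shift
appears as a polarity-signed voltage deflection on one of the channels.

Recordings are exchanged either as delimited text (canonical, header
``h_volts,v_volts,label``) or as a MAT-style container with keys
``horizontal``, ``vertical``, ``labels`` and ``rate``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io as sio

#: Class ids of the five movements. Index = class id.
CLASS_NAMES = ("down", "blink", "up", "left", "right")
CLASS_IDS = {name: i for i, name in enumerate(CLASS_NAMES)}
N_CLASSES = len(CLASS_NAMES)

#: Temporal order of the movement segments in the default recording protocol.
DEFAULT_SEGMENT_ORDER = ("down", "up", "blink", "left", "right")

DEFAULT_SAMPLING_RATE = 650.0
DEFAULT_SAMPLES_PER_SEGMENT = 6500

_UNLABELLED = -1


@dataclass
class EOGRecording:
    """Two aligned voltage series plus sampling metadata and optional labels.

    Parameters
    ----------
    horizontal, vertical
        Channel voltages in volts, equal length.
    sampling_rate
        Samples per second (Hz).
    labels
        Optional per-sample class id in ``{0..4}`` (see :data:`CLASS_NAMES`).
    """

    horizontal: np.ndarray
    vertical: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.horizontal = np.asarray(self.horizontal, dtype=float)
        self.vertical = np.asarray(self.vertical, dtype=float)
        if self.horizontal.ndim != 1 or self.vertical.ndim != 1:
            raise ValueError("channels must be one-dimensional voltage series")
        if self.horizontal.shape != self.vertical.shape:
            raise ValueError(
                "horizontal and vertical channels have different lengths: "
                f"{self.horizontal.size} vs {self.vertical.size}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != self.horizontal.shape:
                raise ValueError("labels length must match the channels")
            bad = (self.labels < 0) | (self.labels >= N_CLASSES)
            if np.any(bad):
                raise ValueError(
                    f"labels must be class ids 0..{N_CLASSES - 1}; "
                    f"got {sorted(set(self.labels[bad]))}"
                )

    @property
    def n_samples(self) -> int:
        return self.horizontal.size

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def is_labelled(self) -> bool:
        return self.labels is not None

    def copy(self) -> "EOGRecording":
        return EOGRecording(
            self.horizontal.copy(),
            self.vertical.copy(),
            self.sampling_rate,
            None if self.labels is None else self.labels.copy(),
        )

    def with_labels(self, labels: np.ndarray | None) -> "EOGRecording":
        return replace(self, labels=labels)


@dataclass
class SegmentTable:
    """Rows of ``(class_id, start, end)`` giving the label of each sample block.

    Rows are normalized to half-open, 0-based ``[start, end)`` blocks and must
    not overlap.
    """

    rows: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        norm = []
        for class_id, start, end in self.rows:
            class_id, start, end = int(class_id), int(start), int(end)
            if not 0 <= class_id < N_CLASSES:
                raise ValueError(f"class id {class_id} out of range 0..{N_CLASSES - 1}")
            if start < 0 or end <= start:
                raise ValueError(f"invalid segment block [{start}, {end})")
            norm.append((class_id, start, end))
        norm.sort(key=lambda r: r[1])
        for (_, _, e0), (_, s1, _) in zip(norm, norm[1:]):
            if s1 < e0:
                raise ValueError("segment rows overlap after normalization")
        self.rows = norm

    @property
    def total_end(self) -> int:
        return self.rows[-1][2] if self.rows else 0


def default_segment_table(
    samples_per_segment: int = DEFAULT_SAMPLES_PER_SEGMENT,
    segment_order: Sequence[str] = DEFAULT_SEGMENT_ORDER,
) -> SegmentTable:
    """The study protocol: contiguous equal blocks in temporal order
    down, up, blink, left, right, labelled with the standard class ids
    (down=0, blink=1, up=2, left=3, right=4)."""
    rows = []
    for i, name in enumerate(segment_order):
        rows.append(
            (CLASS_IDS[name], i * samples_per_segment, (i + 1) * samples_per_segment)
        )
    return SegmentTable(rows)


def apply_segment_table(recording: EOGRecording, table: SegmentTable) -> EOGRecording:
    """Assign per-sample labels from a segment table.

    An empty table returns the recording unlabelled. Samples not covered by
    any row are not permitted (the default protocol covers the recording
    contiguously).
    """
    if not table.rows:
        return recording.with_labels(None)
    if table.total_end > recording.n_samples:
        raise ValueError(
            f"segment table extends to sample {table.total_end} but the "
            f"recording has only {recording.n_samples} samples"
        )
    labels = np.full(recording.n_samples, _UNLABELLED, dtype=int)
    for class_id, start, end in table.rows:
        labels[start:end] = class_id
    if np.any(labels == _UNLABELLED):
        raise ValueError("segment table does not cover the recording contiguously")
    return recording.with_labels(labels)


def _infer_format(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "mat"):
            raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'mat'")
        return fmt
    ext = os.path.splitext(os.fspath(path))[1].lower()
    return "mat" if ext == ".mat" else "csv"


def read_recording(
    path: str | os.PathLike,
    fmt: str | None = None,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> EOGRecording:
    """Read a recording from delimited text or a MAT-style container.

    The CSV dialect is ``h_volts,v_volts[,label]`` with '.' decimal separator;
    a missing or all-empty label column yields an unlabelled recording. CSV
    carries no sampling metadata, so ``sampling_rate`` supplies it; the MAT
    container stores its own ``rate``.
    """
    fmt = _infer_format(path, fmt)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "mat":
        data = sio.loadmat(path)
        for key in ("horizontal", "vertical"):
            if key not in data:
                raise ValueError(f"MAT container is missing channel {key!r}")
        h = np.ravel(data["horizontal"]).astype(float)
        v = np.ravel(data["vertical"]).astype(float)
        rate = float(np.ravel(data["rate"])[0]) if "rate" in data else sampling_rate
        labels = None
        if "labels" in data and np.asarray(data["labels"]).size:
            labels = np.ravel(data["labels"]).astype(int)
        return EOGRecording(h, v, rate, labels)

    frame = pd.read_csv(path)
    for col in ("h_volts", "v_volts"):
        if col not in frame.columns:
            raise ValueError(f"CSV file is missing channel column {col!r}")
    try:
        h = frame["h_volts"].to_numpy(dtype=float)
        v = frame["v_volts"].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric voltage values in {path}") from exc
    labels = None
    if "label" in frame.columns and not frame["label"].isna().all():
        if frame["label"].isna().any():
            raise ValueError("label column is partially missing")
        labels = frame["label"].to_numpy(dtype=int)
    return EOGRecording(h, v, sampling_rate, labels)


def write_recording(
    recording: EOGRecording,
    path: str | os.PathLike,
    fmt: str | None = None,
    overwrite: bool = False,
) -> None:
    """Write a recording; refuses to clobber an existing file unless asked."""
    fmt = _infer_format(path, fmt)
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    if fmt == "mat":
        payload = {
            "horizontal": recording.horizontal,
            "vertical": recording.vertical,
            "rate": recording.sampling_rate,
        }
        if recording.labels is not None:
            payload["labels"] = recording.labels
        sio.savemat(path, payload)
        return
    frame = pd.DataFrame(
        {"h_volts": recording.horizontal, "v_volts": recording.vertical}
    )
    if recording.labels is not None:
        frame["label"] = recording.labels
    frame.to_csv(path, index=False)
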