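"""Readers/writers for six-axis inertial window data.

Two on-disk dialects are supported:

* the public smartphone HAR raw-signal layout: one whitespace-separated
  text file per channel (fixed-length rows, one window per row) plus a
  label file with one integer per row;
* a flattened-window device dialect: one window per text row, laid out as
  six channel blocks ``AX|AY|AZ|GX|GY|GZ`` followed by an integer label.

The canonical in-memory container is :class:`WindowSet`, which every other
module consumes.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

#: Canonical channel order: accelerometer x/y/z (units g), gyroscope x/y/z
#: (units deg/s).  Device frame: x = right, y = down, z = front.
CHANNEL_NAMES = ("AX", "AY", "AZ", "GX", "GY", "GZ")

N_CHANNELS = 6
N_CLASSES = 6

#: Activity classes in canonical order; labels are 1-based in files and
#: 0-based internally.
ACTIVITY_NAMES = (
    "walking",
    "walking_upstairs",
    "walking_downstairs",
    "sitting",
    "standing",
    "laying",
)

#: Published per-activity window counts of the public smartphone dataset
#: (rows: activities in canonical order; columns: train / test /
#: verification).  Used for bookkeeping checks against a local copy.
UCI_SPLIT_COUNTS = {
    "walking": (981, 496, 245),
    "walking_upstairs": (858, 471, 215),
    "walking_downstairs": (789, 420, 197),
    "sitting": (1029, 491, 257),
    "standing": (1099, 532, 275),
    "laying": (1125, 537, 282),
}

_FLAT_FMT = "%.7e"  # scientific notation, 7 decimal digits


@dataclass(frozen=True)
class RecordingMeta:
    """Provenance of a window collection or stream."""

    sampling_rate: float = 50.0
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    participant_id: str = ""
    source: str = "synthetic"  # one of {"uci", "device", "synthetic"}

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if tuple(self.channel_names) != CHANNEL_NAMES:
            raise ValueError(
                f"expected channels {CHANNEL_NAMES}, got {self.channel_names}"
            )
        if self.source not in {"uci", "device", "synthetic"}:
            raise ValueError(f"unknown source {self.source!r}")


@dataclass
class SixAxisRecording:
    """Continuous 6-channel stream with optional per-sample labels.

    ``samples`` is an ``[N, 6]`` array in physical units; ``labels`` (if
    given) holds one 0-based activity label per sample and is used by
    :func:`harfusion.preprocess.segment` to label windows.
    """

    samples: np.ndarray
    meta: RecordingMeta = field(default_factory=RecordingMeta)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_CHANNELS:
            raise ValueError(
                f"samples must be [N, {N_CHANNELS}], got {self.samples.shape}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.samples),):
                raise ValueError("labels must align with samples")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class WindowSet:
    """Fixed-length labelled 6-channel windows — the unit of training.

    ``data`` is ``[n, L, 6]``; ``labels`` are 0-based classes in ``0..5``;
    ``subjects`` holds one participant id per window.
    """

    data: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray | None = None
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3 or self.data.shape[2] != N_CHANNELS:
            raise ValueError(
                f"data must be [n, L, {N_CHANNELS}], got {self.data.shape}"
            )
        if self.labels.shape != (len(self.data),):
            raise ValueError("labels must have one entry per window")
        if len(self.data) and not (
            (self.labels >= 0).all() and (self.labels < N_CLASSES).all()
        ):
            raise ValueError("labels must lie in 0..5 (0-based)")
        if not np.isfinite(self.data).all():
            raise ValueError("windows contain non-finite values")
        if self.subjects is None:
            self.subjects = np.asarray([self.meta.participant_id] * len(self.data))
        else:
            self.subjects = np.asarray(self.subjects)
            if self.subjects.shape != (len(self.data),):
                raise ValueError("subjects must have one entry per window")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def window_len(self) -> int:
        return self.data.shape[1]

    @property
    def class_counts(self) -> dict[int, int]:
        """Map 0-based class -> number of windows."""
        return dict(sorted(Counter(self.labels.tolist()).items()))

    def subset(self, index: Sequence[int] | np.ndarray) -> "WindowSet":
        index = np.asarray(index)
        return WindowSet(
            data=self.data[index],
            labels=self.labels[index],
            subjects=self.subjects[index],
            meta=self.meta,
        )

    def concat(self, other: "WindowSet") -> "WindowSet":
        if other.window_len != self.window_len:
            raise ValueError("window lengths differ")
        return WindowSet(
            data=np.concatenate([self.data, other.data]),
            labels=np.concatenate([self.labels, other.labels]),
            subjects=np.concatenate([self.subjects, other.subjects]),
            meta=self.meta,
        )


# ---------------------------------------------------------------------------
# Public smartphone dataset (raw signals) reader
# ---------------------------------------------------------------------------

_UCI_TOTAL = ("total_acc_x", "total_acc_y", "total_acc_z")
_UCI_BODY = ("body_acc_x", "body_acc_y", "body_acc_z")
_UCI_GYRO = ("body_gyro_x", "body_gyro_y", "body_gyro_z")


def read_uci_inertial(
    directory: str | os.PathLike,
    split: str,
    accel_source: str = "total",
) -> WindowSet:
    """Read one split of the public smartphone raw-signal layout.

    ``directory`` is the split directory (e.g. ``.../train``) containing an
    ``Inertial Signals`` subdirectory with per-channel files
    ``<channel>_<split>.txt`` (128 whitespace-separated values per row, one
    window per row), plus ``y_<split>.txt`` and optionally
    ``subject_<split>.txt``.  ``accel_source`` selects total- or
    body-acceleration channels; gyroscope channels are always included.
    """
    if split not in {"train", "test"}:
        raise ValueError(f"split must be 'train' or 'test', got {split!r}")
    if accel_source not in {"total", "body"}:
        raise ValueError("accel_source must be 'total' or 'body'")
    directory = Path(directory)
    sig_dir = directory / "Inertial Signals"
    if not sig_dir.is_dir():
        sig_dir = directory  # flat fixture layout

    accel = _UCI_TOTAL if accel_source == "total" else _UCI_BODY
    channels = []
    for name in accel + _UCI_GYRO:
        path = sig_dir / f"{name}_{split}.txt"
        if not path.is_file():
            raise FileNotFoundError(f"missing channel file: {path}")
        channels.append(_read_fixed_width_rows(path))

    n_rows = {len(c) for c in channels}
    if len(n_rows) != 1:
        raise ValueError(
            f"row-count mismatch across channel files: {sorted(n_rows)}"
        )
    widths = {c.shape[1] for c in channels}
    if len(widths) != 1:
        raise ValueError(f"window-length mismatch across channels: {sorted(widths)}")

    y_path = directory / f"y_{split}.txt"
    if not y_path.is_file():
        raise FileNotFoundError(f"missing label file: {y_path}")
    if not y_path.read_text().strip():
        raise ValueError(f"label file is empty: {y_path}")
    labels_1based = np.loadtxt(y_path, dtype=int, ndmin=1)
    if len(labels_1based) != len(channels[0]):
        raise ValueError(
            f"label count {len(labels_1based)} != window count {len(channels[0])}"
        )
    if labels_1based.min() < 1 or labels_1based.max() > N_CLASSES:
        bad = labels_1based[(labels_1based < 1) | (labels_1based > N_CLASSES)][0]
        raise ValueError(f"label {bad} outside 1..{N_CLASSES}")

    subj_path = directory / f"subject_{split}.txt"
    subjects = (
        np.loadtxt(subj_path, dtype=int, ndmin=1).astype(str)
        if subj_path.is_file()
        else None
    )

    # row r of channel file c becomes column c of window r
    data = np.stack(channels, axis=2)
    return WindowSet(
        data=data,
        labels=labels_1based - 1,
        subjects=subjects,
        meta=RecordingMeta(source="uci"),
    )


def _read_fixed_width_rows(path: Path) -> np.ndarray:
    rows: list[np.ndarray] = []
    width: int | None = None
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            vals = np.asarray(line.split(), dtype=float)
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise ValueError(
                    f"{path}: row {i} has {len(vals)} values, expected {width}"
                )
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# Flattened-window device dialect
# ---------------------------------------------------------------------------


def read_flat_windows(file: str | os.PathLike, window_len: int) -> WindowSet:
    """Read the device dialect: one window per row, six channel blocks.

    Each row holds ``6 * window_len`` floats (all AX samples, then AY, …,
    then GZ) followed by one 1-based integer label.
    """
    from .preprocess import unflatten_window

    path = Path(file)
    windows, labels = [], []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            *vals, label = parts
            if len(vals) != N_CHANNELS * window_len:
                raise ValueError(
                    f"{path}: row {i} has {len(vals)} values; expected "
                    f"{N_CHANNELS}x{window_len}={N_CHANNELS * window_len}"
                )
            windows.append(unflatten_window(np.asarray(vals, dtype=float), window_len))
            labels.append(int(label))
    if not windows:
        raise ValueError(f"{path}: no windows")
    labels_arr = np.asarray(labels)
    if labels_arr.min() < 1 or labels_arr.max() > N_CLASSES:
        raise ValueError("label outside 1..6 in flat-window file")
    return WindowSet(
        data=np.stack(windows),
        labels=labels_arr - 1,
        meta=RecordingMeta(source="device"),
    )


def write_flat_windows(ws: WindowSet, file: str | os.PathLike) -> Path:
    """Write ``ws`` in the device dialect; inverse of :func:`read_flat_windows`.

    Values are serialized in scientific notation with 7 decimal digits, so a
    round trip agrees with the source to well within 1e-7.
    """
    from .preprocess import flatten_window

    if len(ws) == 0:
        raise ValueError("refusing to write an empty WindowSet")
    path = Path(file)
    with open(path, "w") as fh:
        for w, lab in zip(ws.data, ws.labels):
            flat = flatten_window(w)
            fh.write(" ".join(_FLAT_FMT % v for v in flat))
            fh.write(f" {lab + 1}\n")
    return path


def table1_accounting() -> dict[str, int]:
    """Aggregate the published per-activity split counts.

    Returns totals for the train, test and verification columns plus the
    grand total, as summed from :data:`UCI_SPLIT_COUNTS`.
    """
    train = sum(v[0] for v in UCI_SPLIT_COUNTS.values())
    test = sum(v[1] for v in UCI_SPLIT_COUNTS.values())
    ver = sum(v[2] for v in UCI_SPLIT_COUNTS.values())
    return {
        "train": train,
        "test": test,
        "verification": ver,
        "train_plus_verification": train + ver,
        "total": train + test + ver,
    }
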