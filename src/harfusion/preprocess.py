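"""Raw-count conversion, precision calibration, normalization, windowing
and dataset splitting for six-axis inertial streams.

The pipeline order mirrors acquisition: integer sensor counts are divided
by the LSB sensitivities into g and deg/s, values are calibrated to seven
significant decimal digits, per-channel min-max normalization (fitted on
the training portion only) maps everything into [-1, 1], and continuous
streams are segmented into fixed-length windows with optional overlap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .signal_io import N_CHANNELS, RecordingMeta, SixAxisRecording, WindowSet


@dataclass(frozen=True)
class SensorSpec:
    """LSB sensitivities and full-scale ranges of the 6-axis IMU.

    Defaults are the MPU-6050 at its widest ranges: accelerometer set to
    +/-16 g at 2048 counts/g, gyroscope +/-2000 deg/s at 16.4 counts/(deg/s).
    """

    accel_sensitivity: float = 2048.0  # counts per g
    gyro_sensitivity: float = 16.4  # counts per deg/s
    accel_range: float = 16.0  # +/- g
    gyro_range: float = 2000.0  # +/- deg/s

    def __post_init__(self) -> None:
        if self.accel_sensitivity <= 0 or self.gyro_sensitivity <= 0:
            raise ValueError("sensitivities must be positive")


@dataclass
class NormalizationParams:
    """Per-channel min/max fitted on training data only.

    ``degenerate`` flags channels whose max equals min; those channels are
    mapped to 0 by :func:`normalize`.
    """

    mins: np.ndarray  # shape (6,)
    maxs: np.ndarray  # shape (6,)

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if self.mins.shape != (N_CHANNELS,) or self.maxs.shape != (N_CHANNELS,):
            raise ValueError("mins/maxs must have one value per channel")
        if (self.maxs < self.mins).any():
            raise ValueError("max < min for some channel")

    @property
    def degenerate(self) -> np.ndarray:
        return self.maxs == self.mins


@dataclass(frozen=True)
class SplitSpec:
    """Train/test fractions plus the verification hold-out from the train pool.

    The 70/30 split is taken per class when ``stratified``; the verification
    set is then a ceiling-rounded ``verification_fraction_of_train`` slice of
    the remaining training pool.
    """

    train_fraction: float = 0.7
    test_fraction: float = 0.3
    verification_fraction_of_train: float = 0.2
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isclose(self.train_fraction + self.test_fraction, 1.0):
            raise ValueError("train and test fractions must sum to 1")
        for f in (self.train_fraction, self.test_fraction):
            if not 0 < f < 1:
                raise ValueError("fractions must lie in (0, 1)")
        if not 0 <= self.verification_fraction_of_train < 1:
            raise ValueError("verification fraction must lie in [0, 1)")


def convert_raw(counts: np.ndarray, spec: SensorSpec = SensorSpec()) -> np.ndarray:
    """Convert integer sensor counts to physical units.

    Columns 0-2 are accelerometer counts (divided by counts/g), columns 3-5
    gyroscope counts (divided by counts/(deg/s)).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[-1] != N_CHANNELS:
        raise ValueError(f"expected {N_CHANNELS} channels, got {counts.shape[-1]}")
    out = counts.copy()
    out[..., :3] /= spec.accel_sensitivity
    out[..., 3:] /= spec.gyro_sensitivity
    return out


def calibrate_precision(x: np.ndarray) -> np.ndarray:
    """Round every value to 7 significant decimal digits (round-half-even).

    Harmonizes accelerometer and gyroscope precision so serialized entries
    have identical length in scientific notation.  Idempotent; zeros are
    left untouched.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        idx = np.argwhere(~np.isfinite(x))[0]
        raise ValueError(f"non-finite value at index {tuple(idx)}")
    out = x.copy()
    nz = x != 0
    if nz.any():
        vals = x[nz]
        exponent = np.floor(np.log10(np.abs(vals)))
        factor = 10.0 ** (6 - exponent)
        out[nz] = np.round(vals * factor) / factor
    return out


def fit_minmax(train: WindowSet) -> NormalizationParams:
    """Fit per-channel min/max over all training windows (train data only)."""
    if len(train) == 0:
        raise ValueError("cannot fit normalization on an empty WindowSet")
    mins = train.data.min(axis=(0, 1))
    maxs = train.data.max(axis=(0, 1))
    return NormalizationParams(mins=mins, maxs=maxs)


def normalize(ws: WindowSet, p: NormalizationParams) -> WindowSet:
    """Min-max normalize each channel into [-1, 1].

    Applies ``x' = 2(x - min)/(max - min) - 1`` with fitted train-set
    parameters; out-of-range values (possible on test data) are clipped so
    the stated bound holds literally.  Degenerate channels map to 0.
    """
    if ws.data.shape[2] != len(p.mins):
        raise ValueError("channel count mismatch between WindowSet and params")
    span = p.maxs - p.mins
    safe_span = np.where(p.degenerate, 1.0, span)
    scaled = 2.0 * (ws.data - p.mins) / safe_span - 1.0
    scaled = np.where(p.degenerate, 0.0, scaled)
    scaled = np.clip(scaled, -1.0, 1.0)
    return WindowSet(data=scaled, labels=ws.labels, subjects=ws.subjects, meta=ws.meta)


def segment(
    rec: SixAxisRecording,
    window_seconds: float,
    overlap_fraction: float = 0.0,
    label: int | None = None,
) -> WindowSet:
    """Slide a fixed window over a continuous stream.

    Window length is ``round(window_seconds * sampling_rate)`` and the
    stride ``round(L * (1 - overlap_fraction))``; a stream of N samples
    yields ``floor((N - L)/stride) + 1`` windows.  Labels come from the
    recording's per-sample annotation (windows straddling a label change
    are dropped) or from ``label`` for single-activity recordings.
    """
    fs = rec.meta.sampling_rate
    L = round(window_seconds * fs)
    if L < 1:
        raise ValueError("window length must be at least one sample")
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap fraction must lie in [0, 1)")
    stride = round(L * (1 - overlap_fraction))
    stride = max(stride, 1)
    N = len(rec)
    if N < L:
        warnings.warn(f"stream of {N} samples shorter than window {L}; empty result")
        return WindowSet(
            data=np.empty((0, L, N_CHANNELS)), labels=np.empty(0, dtype=int),
            meta=rec.meta,
        )

    if rec.labels is None and label is None:
        raise ValueError("recording has no annotation and no label was given")

    starts = range(0, N - L + 1, stride)
    windows, labels = [], []
    for s in starts:
        if rec.labels is not None:
            span = rec.labels[s : s + L]
            if (span != span[0]).any():
                continue  # straddles an activity boundary
            lab = int(span[0])
        else:
            lab = int(label)  # type: ignore[arg-type]
        windows.append(rec.samples[s : s + L])
        labels.append(lab)
    data = np.stack(windows) if windows else np.empty((0, L, N_CHANNELS))
    return WindowSet(
        data=data,
        labels=np.asarray(labels, dtype=int),
        subjects=np.asarray([rec.meta.participant_id] * len(windows)),
        meta=rec.meta,
    )


def flatten_window(w: np.ndarray) -> np.ndarray:
    """Flatten an ``[L, 6]`` window into ``[6L]`` channel blocks.

    Layout is channel-blocked: all AX samples, then AY, AZ, GX, GY, GZ —
    a 150-sample window becomes the 1x900 row format.
    """
    w = np.asarray(w)
    if w.ndim != 2 or w.shape[1] != N_CHANNELS:
        raise ValueError(f"expected [L, {N_CHANNELS}] window, got {w.shape}")
    return w.T.reshape(-1)


def unflatten_window(v: np.ndarray, window_len: int) -> np.ndarray:
    """Inverse of :func:`flatten_window`."""
    v = np.asarray(v)
    if v.size != N_CHANNELS * window_len:
        raise ValueError(
            f"vector of {v.size} values is not {N_CHANNELS} blocks of {window_len}"
        )
    return v.reshape(N_CHANNELS, window_len).T


def split_dataset(
    ws: WindowSet, spec: SplitSpec = SplitSpec()
) -> tuple[WindowSet, WindowSet, WindowSet]:
    """Split into (train, verification, test) by the device protocol.

    Per class (when stratified): ``n_test = round(class_n * test_fraction)``;
    the remainder forms the training pool, from which
    ``ceil(pool * verification_fraction_of_train)`` windows are held out for
    verification.  Disjoint, exhaustive, deterministic under ``spec.seed``.
    """
    if len(ws) == 0:
        raise ValueError("cannot split an empty WindowSet")
    rng = np.random.default_rng(spec.seed)

    train_idx: list[np.ndarray] = []
    ver_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []

    if spec.stratified:
        groups = [np.flatnonzero(ws.labels == c) for c in sorted(set(ws.labels))]
        for g in groups:
            if len(g) < 3:
                raise ValueError(
                    f"class with {len(g)} members cannot be split three ways"
                )
    else:
        groups = [np.arange(len(ws))]

    for g in groups:
        perm = rng.permutation(g)
        n_test = round(len(g) * spec.test_fraction)
        test_idx.append(perm[:n_test])
        pool = perm[n_test:]
        n_ver = math.ceil(len(pool) * spec.verification_fraction_of_train)
        ver_idx.append(pool[:n_ver])
        train_idx.append(pool[n_ver:])

    def _collect(parts: list[np.ndarray]) -> np.ndarray:
        return np.sort(np.concatenate(parts)) if parts else np.empty(0, dtype=int)

    return (
        ws.subset(_collect(train_idx)),
        ws.subset(_collect(ver_idx)),
        ws.subset(_collect(test_idx)),
    )


def holdout_verification(
    n_train_pool: int, fraction: float = 0.2
) -> tuple[int, int]:
    """Ceiling hold-out accounting: (n_verification, n_remaining_train).

    A 7,352-entry pool at 20% yields 1,471 verification entries.
    """
    n_ver = math.ceil(n_train_pool * fraction)
    return n_ver, n_train_pool - n_ver


def split_accounting(class_n: int, spec: SplitSpec = SplitSpec()) -> dict[str, int]:
    """Closed-form per-class split sizes under the stratified protocol."""
    n_test = round(class_n * spec.test_fraction)
    pool = class_n - n_test
    n_ver = math.ceil(pool * spec.verification_fraction_of_train)
    return {"train": pool - n_ver, "verification": n_ver, "test": n_test}
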