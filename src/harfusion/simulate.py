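"""Synthetic six-axis IMU signal generator.

Emulates 50 Hz waist-worn accelerometer + gyroscope streams for the six
activities of daily living so the whole pipeline is testable without any
download.  Dynamic activities (walking, upstairs, downstairs) are
gait-periodic: a gravity baseline plus a small harmonic series at a
class-specific stride frequency on each axis, with matching periodic
angular rates.  Static postures are a constant gravity vector plus noise
and slow drift; sitting and standing share the gravity orientation and
differ only in noise scale and a small amplitude offset, making them
deliberately confusable, while laying rotates gravity off the vertical
axis and is easy to separate.

Device frame: x = right, y = down (so gravity is +1 g on AY when
upright), z = front.  Accelerometer in g, gyroscope in deg/s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import segment
from .signal_io import (
    ACTIVITY_NAMES,
    N_CHANNELS,
    RecordingMeta,
    SixAxisRecording,
    WindowSet,
    write_flat_windows,
)

G_STANDARD = 1.0  # gravity magnitude in g units


@dataclass(frozen=True)
class ActivityProfile:
    """Generator parameters for one activity class."""

    label: int  # 0-based class
    gait_frequency: float  # Hz; 0 for static postures
    accel_amplitudes: tuple[float, float, float]  # per-axis, g
    harmonic_weights: tuple[float, ...] = (1.0, 0.5, 0.25)
    gravity_orientation: tuple[float, float, float] = (0.0, 1.0, 0.0)
    gyro_amplitude: float = 0.0  # deg/s
    noise_sd: float = 0.02  # accelerometer channel noise, g
    gyro_noise_sd: float = 1.0  # gyroscope channel noise, deg/s
    drift_sd: float = 0.002  # slow baseline wander scale, g

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.gyro_noise_sd < 0 or self.drift_sd < 0:
            raise ValueError("noise scales must be nonnegative")
        norm = float(np.linalg.norm(self.gravity_orientation))
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError("gravity_orientation must be a unit vector")


def _unit(v: tuple[float, float, float]) -> tuple[float, float, float]:
    a = np.asarray(v, dtype=float)
    a /= np.linalg.norm(a)
    return tuple(a)


def default_profiles() -> dict[int, ActivityProfile]:
    """The stated world: one profile per activity class.

    Gait frequencies 1.8 / 1.4 / 2.2 Hz for walking / upstairs /
    downstairs; sitting and standing share y-down gravity and differ only
    in noise scale and a slight amplitude offset; laying points gravity
    mostly along the front axis.
    """
    return {
        0: ActivityProfile(  # walking
            label=0,
            gait_frequency=1.8,
            accel_amplitudes=(0.25, 0.45, 0.30),
            gyro_amplitude=60.0,
            noise_sd=0.05,
            gyro_noise_sd=4.0,
        ),
        1: ActivityProfile(  # walking upstairs
            label=1,
            gait_frequency=1.4,
            accel_amplitudes=(0.30, 0.55, 0.22),
            harmonic_weights=(1.0, 0.35, 0.15),
            gyro_amplitude=45.0,
            noise_sd=0.06,
            gyro_noise_sd=4.0,
        ),
        2: ActivityProfile(  # walking downstairs
            label=2,
            gait_frequency=2.2,
            accel_amplitudes=(0.35, 0.65, 0.40),
            harmonic_weights=(1.0, 0.70, 0.45),  # sharper heel-strike impacts
            gyro_amplitude=75.0,
            noise_sd=0.07,
            gyro_noise_sd=5.0,
        ),
        3: ActivityProfile(  # sitting
            label=3,
            gait_frequency=0.0,
            accel_amplitudes=(0.010, 0.010, 0.010),
            noise_sd=0.010,
            gyro_noise_sd=0.8,
            drift_sd=0.003,
        ),
        4: ActivityProfile(  # standing: same gravity, slightly larger sway
            label=4,
            gait_frequency=0.0,
            accel_amplitudes=(0.018, 0.012, 0.018),
            noise_sd=0.016,
            gyro_noise_sd=1.2,
            drift_sd=0.004,
        ),
        5: ActivityProfile(  # laying: gravity rotated off the y axis
            label=5,
            gait_frequency=0.0,
            accel_amplitudes=(0.008, 0.008, 0.008),
            gravity_orientation=_unit((0.15, 0.25, 0.95)),
            noise_sd=0.008,
            gyro_noise_sd=0.6,
            drift_sd=0.002,
        ),
    }


@dataclass(frozen=True)
class ProtocolSpec:
    """Data-collection protocol the generator emulates.

    Defaults reproduce the device study's accounting: 21 participants x 6
    activities x 110 non-overlapping 3-s windows at 50 Hz = 13,860 windows
    of 150 samples (900 features when flattened).
    """

    n_participants: int = 21
    windows_per_participant_per_activity: int = 110
    sampling_rate: float = 50.0
    window_seconds: float = 3.0
    overlap_fraction: float = 0.0
    seed: int = 0
    subject_jitter_sd: float = 0.05  # multiplicative amplitude spread
    lowpass_hz: float | None = None  # emulate the on-chip 5 Hz DLPF if set

    def __post_init__(self) -> None:
        if min(self.n_participants, self.windows_per_participant_per_activity) < 1:
            raise ValueError("protocol sizes must be positive")
        if self.sampling_rate <= 0 or self.window_seconds <= 0:
            raise ValueError("rate and window length must be positive")

    @property
    def total_windows(self) -> int:
        return self.n_participants * len(ACTIVITY_NAMES) * (
            self.windows_per_participant_per_activity
        )


def _recording_rng(seed: int, participant: int, label: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(participant, label))
    )


def generate_recording(
    profile: ActivityProfile,
    duration_s: float,
    participant: int = 0,
    seed: int = 0,
    sampling_rate: float = 50.0,
    subject_jitter_sd: float = 0.05,
    lowpass_hz: float | None = None,
) -> SixAxisRecording:
    """Generate one continuous single-activity 6-axis stream.

    Accelerometer = gravity + per-axis harmonic series at the gait
    frequency + Gaussian noise + slow drift; gyroscope = periodic angular
    rate at the gait frequency + noise.  A per-participant multiplicative
    amplitude jitter (~N(1, subject_jitter_sd^2), drawn from the
    participant's own stream) models inter-subject variation.
    Deterministic given (seed, participant, class).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    rng = _recording_rng(seed, participant, profile.label)

    subj_gain = 1.0 + subject_jitter_sd * rng.standard_normal()
    accel = np.tile(
        np.asarray(profile.gravity_orientation) * G_STANDARD, (n, 1)
    )
    gyro = np.zeros((n, 3))

    if profile.gait_frequency > 0:
        f0 = profile.gait_frequency * (1.0 + 0.02 * rng.standard_normal())
        for axis in range(3):
            phase = rng.uniform(0, 2 * np.pi)
            amp = profile.accel_amplitudes[axis] * subj_gain
            for h, w in enumerate(profile.harmonic_weights, start=1):
                accel[:, axis] += amp * w * np.sin(2 * np.pi * f0 * h * t + phase * h)
        for axis, weight in enumerate((1.0, 0.6, 0.8)):
            phase = rng.uniform(0, 2 * np.pi)
            gyro[:, axis] += (
                profile.gyro_amplitude * weight * subj_gain
                * np.sin(2 * np.pi * f0 * t + phase)
            )
        restlessness = 1.0
    else:
        # individuals differ in how still they hold a posture: a
        # per-recording lognormal restlessness gain scales sway and noise,
        # so a fidgety sitter overlaps a calm stander — the deliberate
        # source of sit/stand confusion
        restlessness = rng.lognormal(0.0, 0.25)
        # micro-sway: tiny band-limited oscillation so postures are not
        # pure white noise
        for axis in range(3):
            phase = rng.uniform(0, 2 * np.pi)
            sway_f = rng.uniform(0.2, 0.6)
            accel[:, axis] += (
                profile.accel_amplitudes[axis] * subj_gain * restlessness
                * np.sin(2 * np.pi * sway_f * t + phase)
            )

    if profile.noise_sd > 0:
        accel += rng.normal(0.0, profile.noise_sd * restlessness, size=accel.shape)
    if profile.gyro_noise_sd > 0:
        gyro += rng.normal(0.0, profile.gyro_noise_sd * restlessness, size=gyro.shape)
    if profile.drift_sd > 0:
        # slow random-walk baseline wander, normalized to drift_sd scale
        steps = rng.normal(0.0, 1.0, size=(n, 3))
        walk = np.cumsum(steps, axis=0) / np.sqrt(max(n, 1))
        accel += profile.drift_sd * walk

    samples = np.column_stack([accel, gyro])
    if lowpass_hz is not None:
        samples = _lowpass(samples, lowpass_hz, sampling_rate)

    meta = RecordingMeta(
        sampling_rate=sampling_rate,
        participant_id=f"P{participant:02d}",
        source="synthetic",
    )
    labels = np.full(n, profile.label, dtype=int)
    return SixAxisRecording(samples=samples, meta=meta, labels=labels)


def _lowpass(x: np.ndarray, cutoff_hz: float, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass (DLPF emulation)."""
    from scipy.signal import butter, filtfilt

    b, a = butter(4, cutoff_hz / (fs / 2), btype="low")
    return filtfilt(b, a, x, axis=0)


def generate_dataset(
    protocol: ProtocolSpec = ProtocolSpec(),
    profiles: dict[int, ActivityProfile] | None = None,
) -> WindowSet:
    """Generate the full labelled WindowSet for a protocol.

    Balanced by construction: every participant contributes
    ``windows_per_participant_per_activity`` windows per class.  With the
    default protocol this is 13,860 windows of 150 samples x 6 channels.
    """
    profiles = profiles if profiles is not None else default_profiles()
    L = int(round(protocol.window_seconds * protocol.sampling_rate))
    stride = max(int(round(L * (1 - protocol.overlap_fraction))), 1)
    per_rec = protocol.windows_per_participant_per_activity
    n_samples = L + stride * (per_rec - 1)
    duration = n_samples / protocol.sampling_rate

    parts: list[WindowSet] = []
    for participant in range(protocol.n_participants):
        for label in sorted(profiles):
            rec = generate_recording(
                profiles[label],
                duration_s=duration,
                participant=participant,
                seed=protocol.seed,
                sampling_rate=protocol.sampling_rate,
                subject_jitter_sd=protocol.subject_jitter_sd,
                lowpass_hz=protocol.lowpass_hz,
            )
            ws = segment(
                rec, protocol.window_seconds, protocol.overlap_fraction
            )
            parts.append(ws)

    out = parts[0]
    data = np.concatenate([p.data for p in parts])
    labels = np.concatenate([p.labels for p in parts])
    subjects = np.concatenate([p.subjects for p in parts])
    return WindowSet(data=data, labels=labels, subjects=subjects, meta=out.meta)


def write_device_dataset(
    ws: WindowSet, directory: str | Path, protocol: ProtocolSpec | None = None
) -> dict:
    """Write a WindowSet as device-dialect text plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data_path = write_flat_windows(ws, directory / "windows.txt")
    manifest = {
        "n_windows": len(ws),
        "window_len": ws.window_len,
        "n_features": ws.window_len * N_CHANNELS,
        "class_counts": {str(k + 1): v for k, v in ws.class_counts.items()},
        "data_file": data_path.name,
    }
    if protocol is not None:
        manifest["protocol"] = {
            "n_participants": protocol.n_participants,
            "windows_per_participant_per_activity": (
                protocol.windows_per_participant_per_activity
            ),
            "sampling_rate": protocol.sampling_rate,
            "window_seconds": protocol.window_seconds,
            "seed": protocol.seed,
        }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def write_uci_style(
    ws: WindowSet, directory: str | Path, split: str = "train"
) -> Path:
    """Emit a WindowSet in the public raw-signal directory layout.

    Creates ``Inertial Signals/<channel>_<split>.txt`` per channel plus
    ``y_<split>.txt`` and ``subject_<split>.txt``; used to exercise the
    reader without the real download.
    """
    directory = Path(directory)
    sig_dir = directory / "Inertial Signals"
    sig_dir.mkdir(parents=True, exist_ok=True)
    names = (
        "total_acc_x", "total_acc_y", "total_acc_z",
        "body_gyro_x", "body_gyro_y", "body_gyro_z",
    )
    for c, name in enumerate(names):
        np.savetxt(sig_dir / f"{name}_{split}.txt", ws.data[:, :, c], fmt="%.7e")
    np.savetxt(directory / f"y_{split}.txt", ws.labels + 1, fmt="%d")
    subjects = np.asarray(
        [int("".join(ch for ch in str(s) if ch.isdigit()) or 0) for s in ws.subjects]
    )
    np.savetxt(directory / f"subject_{split}.txt", subjects, fmt="%d")
    return directory
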