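"""Three-zone multi-kernel CNN feature-fusion classifier.

The classifier runs a normalized ``[L, 6]`` inertial window through three
parallel convolutional branches ("zones") that differ only in kernel size
(1, 3 and 5).  Each zone stacks three stride-1 convolutions of 32, 64 and
128 filters — batch-normalized, ReLU-activated, with dropout — and
flattens its output.  Small kernels pick up per-sample channel mixing;
the wider kernels see short local wave shapes, so concatenating the three
flattened zones fuses features at three temporal scales.  Two fully
connected layers (256 and 512 units) and a softmax over the six activity
classes complete the model.

The architecture is length-parametric: any window length supported by the
kernels builds, with only the flatten/concatenation widths changing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .signal_io import N_CHANNELS, N_CLASSES, WindowSet


@dataclass(frozen=True)
class ZoneSpec:
    """One convolutional branch: a kernel size and three filter counts."""

    kernel_size: int
    filters: tuple[int, int, int] = (32, 64, 128)
    stride: int = 1
    padding: str = "same"

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be a positive odd integer")
        if len(self.filters) != 3:
            raise ValueError("each zone has exactly three convolutional stages")
        if not (self.filters[0] < self.filters[1] < self.filters[2]):
            raise ValueError("filter counts must be strictly increasing")
        if self.stride != 1:
            raise ValueError("only stride 1 is supported")
        if self.padding not in {"same", "valid"}:
            raise ValueError("padding must be 'same' or 'valid'")


def default_zones() -> tuple[ZoneSpec, ZoneSpec, ZoneSpec]:
    """Zones A, B, C: kernel sizes 1, 3, 5 with filters 32/64/128."""
    return (ZoneSpec(1), ZoneSpec(3), ZoneSpec(5))


@dataclass(frozen=True)
class ModelConfig:
    """Complete architectural hyperparameter record."""

    window_len: int = 150
    n_channels: int = N_CHANNELS
    zones: tuple[ZoneSpec, ...] = field(default_factory=default_zones)
    fc_widths: tuple[int, int] = (256, 512)
    dropout_rate: float = 0.3
    n_classes: int = N_CLASSES
    batch_norm: bool = True
    dropout_in_zones: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes != N_CLASSES:
            raise ValueError(f"model is defined for {N_CLASSES} activity classes")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not self.zones:
            raise ValueError("at least one zone required")
        if self.window_len < 1:
            raise ValueError("window_len must be positive")

    def zone_flat_width(self, zone: ZoneSpec) -> int:
        """Flattened width of one zone's output for this window length."""
        L = self.window_len
        for _ in zone.filters:
            out = L if zone.padding == "same" else L - zone.kernel_size + 1
            if out < 1:
                raise ValueError(
                    f"window of {self.window_len} too short for kernel "
                    f"{zone.kernel_size} under valid padding"
                )
            L = out
        return L * zone.filters[-1]

    @property
    def concat_width(self) -> int:
        """Width of the fused feature vector entering the first FC layer."""
        return sum(self.zone_flat_width(z) for z in self.zones)

    def to_dict(self) -> dict:
        return {
            "window_len": self.window_len,
            "n_channels": self.n_channels,
            "zones": [
                {
                    "kernel_size": z.kernel_size,
                    "filters": list(z.filters),
                    "stride": z.stride,
                    "padding": z.padding,
                }
                for z in self.zones
            ],
            "fc_widths": list(self.fc_widths),
            "dropout_rate": self.dropout_rate,
            "n_classes": self.n_classes,
            "batch_norm": self.batch_norm,
            "dropout_in_zones": self.dropout_in_zones,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        zones = tuple(
            ZoneSpec(
                kernel_size=z["kernel_size"],
                filters=tuple(z["filters"]),
                stride=z["stride"],
                padding=z["padding"],
            )
            for z in d["zones"]
        )
        return cls(
            window_len=d["window_len"],
            n_channels=d["n_channels"],
            zones=zones,
            fc_widths=tuple(d["fc_widths"]),
            dropout_rate=d["dropout_rate"],
            n_classes=d["n_classes"],
            batch_norm=d["batch_norm"],
            dropout_in_zones=d["dropout_in_zones"],
            seed=d["seed"],
        )


class FusionModel:
    """The assembled network: parallel zones, concatenation, FC head."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        init_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
        # independent stream so dropout draws don't disturb init reproducibility
        self.dropout_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,))
        )
        self.zones = [self._build_zone(z, init_rng) for z in cfg.zones]
        self.head = self._build_head(init_rng)
        self._zone_shapes: list[tuple] = []

    def _build_zone(self, z: ZoneSpec, rng: np.random.Generator) -> nn.Sequential:
        cfg = self.cfg
        layers: list[nn.Layer] = []
        in_ch = cfg.n_channels
        for n_filters in z.filters:
            layers.append(
                nn.Conv1D(in_ch, n_filters, z.kernel_size, padding=z.padding, rng=rng)
            )
            if cfg.batch_norm:
                layers.append(nn.BatchNorm(n_filters))
            layers.append(nn.ReLU())
            if cfg.dropout_in_zones and cfg.dropout_rate > 0:
                layers.append(nn.Dropout(cfg.dropout_rate, rng=self.dropout_rng))
            in_ch = n_filters
        layers.append(nn.Flatten())
        return nn.Sequential(layers)

    def _build_head(self, rng: np.random.Generator) -> nn.Sequential:
        cfg = self.cfg
        layers: list[nn.Layer] = []
        in_w = cfg.concat_width
        for width in cfg.fc_widths:
            layers.append(nn.Dense(in_w, width, rng=rng))
            if cfg.batch_norm:
                layers.append(nn.BatchNorm(width))
            layers.append(nn.ReLU())
            if cfg.dropout_rate > 0:
                layers.append(nn.Dropout(cfg.dropout_rate, rng=self.dropout_rng))
            in_w = width
        layers.append(nn.Dense(in_w, cfg.n_classes, rng=rng))
        return nn.Sequential(layers)

    # -- parameter plumbing -------------------------------------------------

    @property
    def params(self) -> list[np.ndarray]:
        return [p for z in self.zones for p in z.params] + self.head.params

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for z in self.zones for g in z.grads] + self.head.grads

    def n_params(self) -> int:
        """Trainable parameter count (conv/dense weights+biases, BN gamma/beta)."""
        return int(sum(p.size for p in self.params))

    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for p in self.params]
        for layer in self._all_layers():
            if isinstance(layer, nn.BatchNorm):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        n = len(self.params)
        for p, s in zip(self.params, state[:n]):
            p[...] = s
        rest = iter(state[n:])
        for layer in self._all_layers():
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean[...] = next(rest)
                layer.running_var[...] = next(rest)

    def _all_layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = []
        for z in self.zones:
            out.extend(z.layers)
        out.extend(self.head.layers)
        return out

    # -- forward / backward -------------------------------------------------

    def forward_logits(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        batch = np.asarray(batch, dtype=nn.DTYPE)
        if batch.ndim != 3 or batch.shape[2] != self.cfg.n_channels:
            raise ValueError(
                f"batch must be [B, L, {self.cfg.n_channels}], got {batch.shape}"
            )
        outs = [z.forward(batch, train) for z in self.zones]
        self._zone_widths = [o.shape[1] for o in outs]
        fused = np.concatenate(outs, axis=1)
        return self.head.forward(fused, train)

    def backward(self, grad_logits: np.ndarray) -> None:
        grad = self.head.backward(grad_logits)
        offset = 0
        for z, w in zip(self.zones, self._zone_widths):
            z.backward(grad[:, offset : offset + w])
            offset += w


def build_model(cfg: ModelConfig) -> FusionModel:
    """Construct the fusion classifier; fails fast on impossible geometry."""
    cfg.concat_width  # raises if a zone cannot consume the window
    return FusionModel(cfg)


def forward(model: FusionModel, batch: np.ndarray) -> np.ndarray:
    """Inference-mode class probabilities, one row per window.

    Dropout is inactive and batch statistics frozen, so identical inputs
    give identical outputs; each row is nonnegative and sums to 1.
    """
    return nn.softmax(model.forward_logits(batch, train=False))


def predict(model: FusionModel, ws: WindowSet | np.ndarray) -> np.ndarray:
    """0-based predicted labels: argmax probability, ties to the lowest class."""
    batch = ws.data if isinstance(ws, WindowSet) else np.asarray(ws)
    probs = forward(model, batch)
    return probs.argmax(axis=1)


# ---------------------------------------------------------------------------
# Checkpointing: binary weights + sidecar JSON manifest
# ---------------------------------------------------------------------------


def save_checkpoint(
    model: FusionModel, path: str | Path, extra: dict | None = None
) -> Path:
    """Write weights (npz) and a JSON manifest sufficient to rebuild."""
    path = Path(path)
    state = model.get_state()
    np.savez(path.with_suffix(".npz"), *state)
    manifest = {"config": model.cfg.to_dict(), "n_arrays": len(state)}
    manifest.update(extra or {})
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))
    return path.with_suffix(".npz")


def load_checkpoint(path: str | Path) -> FusionModel:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig.from_dict(manifest["config"])
    model = build_model(cfg)
    with np.load(path.with_suffix(".npz")) as npz:
        state = [npz[k] for k in npz.files]
    model.set_state(state)
    return model
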