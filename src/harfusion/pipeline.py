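"""End-to-end runs: simulate -> preprocess/split -> train -> evaluate / CV.

This is the orchestration surface the example scripts drive.  Every run
writes a JSON manifest (config, seed, input checksum) into its output
directory so results are reproducible and attributable; no step mutates
its inputs.  Configuration can be loaded from a YAML file whose keys
mirror the dataclass fields, with explicit keyword overrides taking
precedence over the file, which takes precedence over defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .evaluation import CVConfig, MetricsReport, confusion, kfold_cv, metrics_report
from .fusion_model import FusionModel, ModelConfig, build_model, predict, save_checkpoint
from .preprocess import SensorSpec, SplitSpec, fit_minmax, normalize, split_dataset
from .signal_io import WindowSet
from .simulate import ProtocolSpec, generate_dataset, write_device_dataset
from .training import TrainConfig, TrainHistory, train


@dataclass(frozen=True)
class RunConfig:
    """One experiment: dataset source, splits, model, training, CV, output."""

    protocol: ProtocolSpec = ProtocolSpec()
    split: SplitSpec = SplitSpec()
    sensor: SensorSpec = SensorSpec()
    train_cfg: TrainConfig = TrainConfig()
    cv: CVConfig = CVConfig()
    window_len: int | None = None  # derived from protocol when None
    seed: int = 0

    def model_cfg(self) -> ModelConfig:
        L = self.window_len or int(
            round(self.protocol.window_seconds * self.protocol.sampling_rate)
        )
        return ModelConfig(window_len=L, seed=self.seed)


def load_run_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from YAML + overrides (overrides > file > defaults)."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    sections = {
        "protocol": ProtocolSpec,
        "split": SplitSpec,
        "sensor": SensorSpec,
        "train_cfg": TrainConfig,
        "cv": CVConfig,
    }
    kwargs: dict = {}
    for key, cls in sections.items():
        if key in raw:
            val = raw.pop(key)
            kwargs[key] = val if isinstance(val, cls) else cls(**val)
    kwargs.update(raw)
    return RunConfig(**kwargs)


def _checksum(ws: WindowSet) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(ws.data).tobytes())
    h.update(np.ascontiguousarray(ws.labels).tobytes())
    return h.hexdigest()[:16]


def _write_manifest(out_dir: Path, name: str, payload: dict) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path


def run_simulate(cfg: RunConfig, out_dir: str | Path) -> WindowSet:
    """Generate a synthetic dataset and write it in the device dialect."""
    out_dir = Path(out_dir)
    ws = generate_dataset(cfg.protocol)
    manifest = write_device_dataset(ws, out_dir, cfg.protocol)
    manifest["checksum"] = _checksum(ws)
    _write_manifest(out_dir, "run_manifest.json", {"stage": "simulate", **manifest})
    return ws


def prepare_splits(
    ws: WindowSet, cfg: RunConfig
) -> tuple[WindowSet, WindowSet, WindowSet]:
    """Split then normalize with train-fitted parameters (no leakage)."""
    train_ws, ver_ws, test_ws = split_dataset(ws, cfg.split)
    params = fit_minmax(train_ws)
    return (
        normalize(train_ws, params),
        normalize(ver_ws, params),
        normalize(test_ws, params),
    )


def run_train(
    ws: WindowSet, cfg: RunConfig, out_dir: str | Path
) -> tuple[FusionModel, TrainHistory, MetricsReport]:
    """Split, train with early stopping, evaluate on the held-out test set."""
    out_dir = Path(out_dir)
    train_ws, ver_ws, test_ws = prepare_splits(ws, cfg)
    model = build_model(cfg.model_cfg())
    model, history = train(model, train_ws, ver_ws, cfg.train_cfg)
    report = run_evaluate(model, test_ws, out_dir)

    out_dir.mkdir(parents=True, exist_ok=True)
    history.to_frame().to_csv(out_dir / "history.csv", index=False)
    save_checkpoint(model, out_dir / "model", extra={"best_epoch": history.best_epoch})
    _write_manifest(
        out_dir,
        "run_manifest.json",
        {
            "stage": "train",
            "seed": cfg.seed,
            "checksum": _checksum(ws),
            "model_cfg": cfg.model_cfg().to_dict(),
            "train_cfg": asdict(cfg.train_cfg),
            "epochs_run": history.n_epochs,
            "best_epoch": history.best_epoch,
            "test_accuracy": report.accuracy,
        },
    )
    return model, history, report


def run_evaluate(
    model: FusionModel, test_ws: WindowSet, out_dir: str | Path
) -> MetricsReport:
    """Predict on a normalized test set; write metrics + confusion matrix."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cm = confusion(test_ws.labels, predict(model, test_ws))
    report = metrics_report(cm)
    cm.to_csv(out_dir / "confusion.csv")
    report.to_json(out_dir / "metrics.json")
    return report


def run_cv(
    ws: WindowSet, cfg: RunConfig, out_dir: str | Path
) -> tuple[list[MetricsReport], MetricsReport, float]:
    """Merged-data k-fold cross-validation with per-fold reports."""
    out_dir = Path(out_dir)
    train_ws, ver_ws, test_ws = split_dataset(ws, cfg.split)
    merged = train_ws.concat(ver_ws).concat(test_ws)
    params = fit_minmax(merged)  # merged protocol: all data pooled
    merged = normalize(merged, params)
    reports, pooled, mean_acc = kfold_cv(
        merged, cfg.model_cfg(), cfg.train_cfg, cfg.cv
    )
    _write_manifest(
        out_dir,
        "run_manifest.json",
        {
            "stage": "cv",
            "seed": cfg.seed,
            "checksum": _checksum(ws),
            "k": cfg.cv.k,
            "fold_accuracy": [r.accuracy for r in reports],
            "mean_accuracy": mean_acc,
            "pooled_accuracy": pooled.accuracy,
        },
    )
    for i, r in enumerate(reports):
        r.to_json(out_dir / f"fold_{i:02d}_metrics.json")
    pooled.to_json(out_dir / "pooled_metrics.json")
    return reports, pooled, mean_acc
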