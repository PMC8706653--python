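"""Classification metrics and the merged-data k-fold protocol.

Metrics follow the standard one-vs-rest decomposition of a 6x6 confusion
matrix: per-class precision TP/(TP+FP) and recall TP/(TP+FN), their
unweighted (macro) means, overall accuracy as the diagonal fraction, and
an F1 computed as the harmonic mean of the two macro values.  All values
are reported in percent.  Counts stay exact integers until the final
percentage, so the brute-force tally and this implementation agree bit
for bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .fusion_model import FusionModel, ModelConfig, build_model, predict
from .signal_io import N_CLASSES, WindowSet
from .training import TrainConfig, train


@dataclass
class ConfusionMatrix:
    """6x6 count table: rows true class, columns predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self, i: int) -> int:
        return int(self.counts[i, i])

    def fp(self, i: int) -> int:
        return int(self.counts[:, i].sum() - self.counts[i, i])

    def fn(self, i: int) -> int:
        return int(self.counts[i, :].sum() - self.counts[i, i])

    def tn(self, i: int) -> int:
        return self.total - self.tp(i) - self.fp(i) - self.fn(i)

    def to_csv(self, path: str | Path) -> Path:
        import pandas as pd

        path = Path(path)
        pd.DataFrame(self.counts).to_csv(path, index=False)
        return path

    def to_heatmap(self, path: str | Path) -> Path:
        """Write the count table as an annotated heatmap figure."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        from .signal_io import ACTIVITY_NAMES

        fig, ax = plt.subplots(figsize=(6, 5))
        ax.imshow(self.counts, cmap="Blues")
        n = self.n_classes
        names = ACTIVITY_NAMES[:n] if n <= len(ACTIVITY_NAMES) else range(n)
        ax.set_xticks(range(n), names, rotation=45, ha="right")
        ax.set_yticks(range(n), names)
        ax.set(xlabel="predicted", ylabel="true", title="Confusion matrix")
        for i in range(n):
            for j in range(n):
                ax.text(j, i, str(self.counts[i, j]), ha="center", va="center")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return Path(path)


@dataclass
class MetricsReport:
    """All headline metrics in percent, plus per-class detail."""

    accuracy: float
    precision: list[float]
    recall: list[float]
    p_macro: float
    r_macro: float
    f1: float
    f1_per_class_macro: float
    degenerate_classes: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path


@dataclass(frozen=True)
class CVConfig:
    k: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")


def confusion(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = N_CLASSES) -> ConfusionMatrix:
    """Tally a confusion matrix from 0-based label vectors."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if len(y_true) and (
        y_true.min() < 0
        or y_true.max() >= n_classes
        or y_pred.min() < 0
        or y_pred.max() >= n_classes
    ):
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy in percent: 100 x diagonal / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * cm.counts.trace() / cm.total


def one_vs_rest_accuracy(cm: ConfusionMatrix) -> float:
    """Mean per-class binary accuracy 100 x (TP_i+TN_i)/total.

    The binary TP/TN reading of the accuracy formula averaged over classes;
    exposed separately from the standard multiclass :func:`accuracy`.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    vals = [100.0 * (cm.tp(i) + cm.tn(i)) / cm.total for i in range(cm.n_classes)]
    return float(np.mean(vals))


def macro_precision_recall(
    cm: ConfusionMatrix,
) -> tuple[float, float, list[float], list[float], list[int]]:
    """Per-class precision/recall and their unweighted macro means (percent).

    Classes with a zero denominator (never predicted / never present)
    contribute 0 and are listed in the returned ``degenerate`` flags.
    """
    precision, recall, degenerate = [], [], []
    for i in range(cm.n_classes):
        tp, fp, fn = cm.tp(i), cm.fp(i), cm.fn(i)
        if tp + fp == 0 or tp + fn == 0:
            degenerate.append(i)
        precision.append(100.0 * tp / (tp + fp) if tp + fp else 0.0)
        recall.append(100.0 * tp / (tp + fn) if tp + fn else 0.0)
    if degenerate:
        warnings.warn(f"degenerate classes (zero denominator): {degenerate}")
    return (
        float(np.mean(precision)),
        float(np.mean(recall)),
        precision,
        recall,
        degenerate,
    )


def f1_from_macros(p_macro: float, r_macro: float) -> float:
    """Harmonic mean of the macro precision and macro recall (percent)."""
    if p_macro + r_macro == 0:
        return 0.0
    return 2.0 * p_macro * r_macro / (p_macro + r_macro)


def macro_f1_per_class(cm: ConfusionMatrix) -> float:
    """Alternative F1: unweighted mean of per-class harmonic means."""
    _, _, precision, recall, _ = _silent_macro(cm)
    per_class = [
        2 * p * r / (p + r) if p + r else 0.0 for p, r in zip(precision, recall)
    ]
    return float(np.mean(per_class))


def _silent_macro(cm: ConfusionMatrix):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return macro_precision_recall(cm)


def metrics_report(cm: ConfusionMatrix) -> MetricsReport:
    """Assemble the full report from one confusion matrix."""
    p_macro, r_macro, precision, recall, degenerate = _silent_macro(cm)
    return MetricsReport(
        accuracy=accuracy(cm),
        precision=precision,
        recall=recall,
        p_macro=p_macro,
        r_macro=r_macro,
        f1=f1_from_macros(p_macro, r_macro),
        f1_per_class_macro=macro_f1_per_class(cm),
        degenerate_classes=degenerate,
    )


def kfold_indices(
    labels: np.ndarray, cv: CVConfig
) -> list[np.ndarray]:
    """Assign every index to exactly one of k near-equal test folds.

    Stratified mode deals each class's shuffled members round-robin across
    folds so per-fold class proportions match the pool; unstratified mode
    splits a single shuffled permutation into k contiguous chunks ("k equal
    parts").  Deterministic under ``cv.seed``.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if cv.k > n:
        raise ValueError(f"k={cv.k} exceeds dataset size {n}")
    rng = np.random.default_rng(cv.seed)
    folds: list[list[int]] = [[] for _ in range(cv.k)]
    if cv.stratified:
        start = 0
        for c in sorted(set(labels.tolist())):
            members = rng.permutation(np.flatnonzero(labels == c))
            for j, idx in enumerate(members):
                folds[(start + j) % cv.k].append(int(idx))
            start += len(members)  # rotate so small classes spread evenly
    else:
        perm = rng.permutation(n)
        # chunk sizes differ by at most 1
        sizes = np.full(cv.k, n // cv.k)
        sizes[: n % cv.k] += 1
        pos = 0
        for j, size in enumerate(sizes):
            folds[j] = perm[pos : pos + size].tolist()
            pos += size
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def kfold_cv(
    ws: WindowSet,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    cv: CVConfig = CVConfig(),
    verification_fraction: float = 0.1,
    verbose: bool = False,
) -> tuple[list[MetricsReport], MetricsReport, float]:
    """Merged-data k-fold cross-validation.

    The pooled WindowSet is divided into k near-equal folds; each fold in
    turn is the test set while a fresh model is trained on the rest (with a
    ``verification_fraction`` slice of the training part held out for early
    stopping).  Returns per-fold reports, a pooled report over all
    out-of-fold predictions, and the mean fold accuracy.
    """
    folds = kfold_indices(ws.labels, cv)
    all_idx = np.arange(len(ws))
    reports: list[MetricsReport] = []
    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []

    for fold_no, test_idx in enumerate(folds):
        train_mask = np.ones(len(ws), dtype=bool)
        train_mask[test_idx] = False
        pool_idx = all_idx[train_mask]
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cv.seed, spawn_key=(fold_no,))
        )
        perm = rng.permutation(pool_idx)
        n_ver = max(1, int(np.ceil(len(perm) * verification_fraction)))
        ver_idx, tr_idx = perm[:n_ver], perm[n_ver:]

        model = build_model(model_cfg)
        model, _ = train(model, ws.subset(tr_idx), ws.subset(ver_idx), train_cfg)
        y_pred = predict(model, ws.subset(test_idx))
        y_true = ws.labels[test_idx]
        reports.append(metrics_report(confusion(y_true, y_pred)))
        pooled_true.append(y_true)
        pooled_pred.append(y_pred)
        if verbose:
            print(f"fold {fold_no + 1}/{cv.k}: accuracy {reports[-1].accuracy:.2f}%")

    pooled = metrics_report(
        confusion(np.concatenate(pooled_true), np.concatenate(pooled_pred))
    )
    mean_acc = float(np.mean([r.accuracy for r in reports]))
    return reports, pooled, mean_acc
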