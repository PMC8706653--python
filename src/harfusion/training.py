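"""Training protocol: Adam, categorical cross-entropy, plateau learning-rate
decay with a hard floor, early stopping with best-model retention.

The learning rate starts at 1e-3 and halves whenever the verification loss
has not improved for ``lr_decay_patience`` epochs, never dropping below
1e-7.  Training stops early once the verification loss has not improved
for ``early_stop_patience`` epochs (or at ``max_epochs``), and the
returned model carries the parameters of the best-verification-loss epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .fusion_model import FusionModel
from .signal_io import WindowSet


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    lr_floor: float = 1e-7
    max_epochs: int = 1000
    batch_size: int = 64
    early_stop_patience: int = 50
    lr_decay_factor: float = 0.5
    lr_decay_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_floor > self.learning_rate:
            raise ValueError("lr_floor must not exceed the learning rate")
        if self.early_stop_patience < 1 or self.lr_decay_patience < 1:
            raise ValueError("patience values must be >= 1")
        if not 0 < self.lr_decay_factor < 1:
            raise ValueError("lr_decay_factor must lie in (0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")


@dataclass
class TrainHistory:
    """Per-epoch curves plus the bookkeeping of the retained model."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    ver_loss: list[float] = field(default_factory=list)
    ver_acc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = 0  # 0-based index of the best verification loss

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    @property
    def final_lr(self) -> float:
        return self.lr[-1] if self.lr else float("nan")

    def to_frame(self):
        """History as a pandas DataFrame (epoch, lr, losses, accuracies)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, self.n_epochs + 1),
                "lr": self.lr,
                "train_loss": self.train_loss,
                "train_acc": self.train_acc,
                "ver_loss": self.ver_loss,
                "ver_acc": self.ver_acc,
            }
        )


def plot_history(history: "TrainHistory", path) -> None:
    """Write accuracy and loss curves (train vs verification) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_acc, ax_loss) = plt.subplots(1, 2, figsize=(10, 4))
    epochs = range(1, history.n_epochs + 1)
    ax_acc.plot(epochs, history.train_acc, label="train")
    ax_acc.plot(epochs, history.ver_acc, label="verification")
    ax_acc.set(xlabel="epoch", ylabel="accuracy", title="Model accuracy")
    ax_acc.legend()
    ax_loss.plot(epochs, history.train_loss, label="train")
    ax_loss.plot(epochs, history.ver_loss, label="verification")
    ax_loss.set(xlabel="epoch", ylabel="loss", title="Model loss")
    ax_loss.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cross_entropy(
    probabilities: np.ndarray, labels: np.ndarray, eps: float = 1e-12
) -> float:
    """Mean categorical cross-entropy of probability rows vs true labels.

    ``labels`` are 0-based integers.  A zero probability at the true class
    is clamped at ``eps`` so the loss stays finite; the loss is 0 exactly
    for perfectly confident correct predictions.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probabilities.ndim != 2 or len(probabilities) != len(labels):
        raise ValueError("probabilities must be [n, k] aligned with labels")
    p_true = probabilities[np.arange(len(labels)), labels]
    return float(-np.log(np.maximum(p_true, eps)).mean())


def _evaluate(model: FusionModel, ws: WindowSet, batch_size: int) -> tuple[float, float]:
    """Inference-mode mean loss and accuracy over a WindowSet."""
    losses, correct = [], 0
    for s in range(0, len(ws), batch_size):
        xb = ws.data[s : s + batch_size]
        yb = ws.labels[s : s + batch_size]
        logits = model.forward_logits(xb, train=False)
        loss, _ = nn.softmax_cross_entropy(logits, yb)
        losses.append(loss * len(yb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(ws)), correct / len(ws)


def train(
    model: FusionModel,
    train_set: WindowSet,
    verification: WindowSet,
    cfg: TrainConfig = TrainConfig(),
    verbose: bool = False,
) -> tuple[FusionModel, TrainHistory]:
    """Fit the model; returns it restored to the best-verification epoch.

    Inputs must already be normalized and disjoint.  Deterministic given
    ``cfg.seed`` (batch shuffling) and the model's own seed (init,
    dropout), in single-threaded BLAS mode.
    """
    if len(verification) == 0:
        raise ValueError("verification set is empty; early stopping undefined")
    if len(train_set) == 0:
        raise ValueError("training set is empty")

    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(2,)))
    opt = nn.Adam(model.params, model.grads, lr=cfg.learning_rate)
    history = TrainHistory()

    best_loss = np.inf
    best_state = model.get_state()
    epochs_since_best = 0
    epochs_since_decay_best = 0
    lr = cfg.learning_rate

    x = train_set.data.astype(nn.DTYPE)
    y = train_set.labels

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x))
        epoch_loss, correct = 0.0, 0
        for s in range(0, len(x), cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward_logits(xb, train=True)
            loss, grad = nn.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(f"NaN/inf loss at epoch {epoch + 1}")
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(yb)
            correct += int((logits.argmax(axis=1) == yb).sum())

        ver_loss, ver_acc = _evaluate(model, verification, cfg.batch_size)
        history.train_loss.append(epoch_loss / len(x))
        history.train_acc.append(correct / len(x))
        history.ver_loss.append(ver_loss)
        history.ver_acc.append(ver_acc)
        history.lr.append(lr)
        if verbose:
            print(
                f"epoch {epoch + 1:4d}  lr {lr:.2e}  "
                f"train loss {history.train_loss[-1]:.4f} acc {history.train_acc[-1]:.3f}  "
                f"ver loss {ver_loss:.4f} acc {ver_acc:.3f}"
            )

        if ver_loss < best_loss:
            best_loss = ver_loss
            best_state = model.get_state()
            history.best_epoch = epoch
            epochs_since_best = 0
            epochs_since_decay_best = 0
        else:
            epochs_since_best += 1
            epochs_since_decay_best += 1

        if epochs_since_best >= cfg.early_stop_patience:
            break

        if epochs_since_decay_best >= cfg.lr_decay_patience:
            new_lr = max(lr * cfg.lr_decay_factor, cfg.lr_floor)
            if new_lr < lr:
                lr = new_lr
                opt.lr = lr
            epochs_since_decay_best = 0

    model.set_state(best_state)
    return model, history
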