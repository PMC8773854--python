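"""Within-subject training loop with best-checkpoint restoration.

The recipe: Adam (learning rate 0.0009), batch size 64, categorical
cross-entropy, up to 1000 epochs, and a per-epoch callback that snapshots
the weights whenever the monitored accuracy improves; the best snapshot is
restored before evaluation.

``monitor_split`` selects what the callback watches.  ``"eval"``
reproduces the published protocol of monitoring the held-out session —
note this lets the checkpoint selection see the evaluation data, an
optimistic-bias risk that is documented rather than hidden —
``"train"`` keeps the evaluation session completely unseen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epochs import EpochSet
from .errors import TrainingError, ValidationError
from .metrics import EvalReport, confusion_matrix, metrics_from_cm
from .nn import Adam, SGD, softmax_cross_entropy
from .nn.model import MultibranchClassifier

__all__ = ["TrainConfig", "TrainHistory", "train", "evaluate"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults follow the standard recipe)."""

    epochs: int = 1000
    batch_size: int = 64
    learning_rate: float = 0.0009
    optimizer: str = "adam"  # "adam" | "sgd"
    log_base: float = np.e
    monitor_split: str = "eval"  # "eval" | "train"
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")
        if not self.learning_rate >= 0:
            raise ValidationError("learning_rate must be non-negative")
        if self.optimizer not in ("adam", "sgd"):
            raise ValidationError(f"optimizer must be 'adam' or 'sgd', got {self.optimizer!r}")
        if self.monitor_split not in ("eval", "train"):
            raise ValidationError(f"monitor_split must be 'eval' or 'train', got {self.monitor_split!r}")


@dataclass
class TrainHistory:
    """Per-epoch loss/accuracy series and the best-checkpoint bookkeeping."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    monitor_loss: list[float] = field(default_factory=list)
    monitor_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_monitor_accuracy: float = -np.inf

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "train_loss": self.train_loss,
                "train_accuracy": self.train_accuracy,
                "monitor_loss": self.monitor_loss,
                "monitor_accuracy": self.monitor_accuracy,
            }
        )


def _check_compat(model: MultibranchClassifier, epochs: EpochSet, role: str) -> None:
    if epochs.n_trials == 0:
        raise ValidationError(f"{role} set is empty")
    if epochs.labels.size and int(epochs.labels.max()) >= model.n_classes:
        raise ValidationError(
            f"{role} labels reach {int(epochs.labels.max())} but the model has {model.n_classes} classes"
        )
    if model.input_shape is not None and epochs.data.shape[1:] != model.input_shape:
        raise ValidationError(
            f"{role} epochs have shape {epochs.data.shape[1:]} but the model "
            f"was built for {model.input_shape}"
        )


def _monitor_pass(model, x, labels, log_base, batch_size=64):
    probs = model.predict_proba(x, batch_size=batch_size)
    eps = np.finfo(probs.dtype).tiny
    loss = float(-np.log(probs[np.arange(len(labels)), labels] + eps).mean() / np.log(log_base))
    acc = float((np.argmax(probs, axis=1) == labels).mean())
    return loss, acc


def train(
    model: MultibranchClassifier,
    train_set: EpochSet,
    monitor_set: EpochSet,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[MultibranchClassifier, TrainHistory]:
    """Train ``model`` and restore the weights of the best monitored epoch.

    Data order is reshuffled every epoch with a generator seeded by
    ``cfg.seed``; two runs with the same seed (and freshly built identical
    models) produce identical histories.  Ties in monitored accuracy keep
    the earliest epoch.
    """
    cfg.validate()
    _check_compat(model, train_set, "train")
    _check_compat(model, monitor_set, "monitor")

    x = np.ascontiguousarray(train_set.data)
    y = train_set.labels.astype(np.int64)
    xm = np.ascontiguousarray(monitor_set.data)
    ym = monitor_set.labels.astype(np.int64)
    monitor_on_train = cfg.monitor_split == "train"

    params = model.params()
    opt = Adam(params, lr=cfg.learning_rate) if cfg.optimizer == "adam" else SGD(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    hist = TrainHistory()
    best_state = model.get_state()

    n = x.shape[0]
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward(xb, training=True, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, yb, cfg.log_base)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            losses.append(loss * len(idx))
            correct += int((np.argmax(logits, axis=1) == yb).sum())
            for p in params:
                p.zero_grad()
            model.backward(dlogits)
            opt.step()
        hist.train_loss.append(float(np.sum(losses) / n))
        hist.train_accuracy.append(correct / n)

        if monitor_on_train:
            mloss, macc = _monitor_pass(model, x, y, cfg.log_base)
        else:
            mloss, macc = _monitor_pass(model, xm, ym, cfg.log_base)
        hist.monitor_loss.append(mloss)
        hist.monitor_accuracy.append(macc)
        if macc > hist.best_monitor_accuracy:
            hist.best_monitor_accuracy = macc
            hist.best_epoch = epoch
            best_state = model.get_state()

    model.set_state(best_state)
    return model, hist


def evaluate(
    model: MultibranchClassifier,
    test_set: EpochSet,
    pe_mode: str = "marginals",
) -> tuple[np.ndarray, EvalReport]:
    """Per-trial argmax predictions and the derived metric report."""
    _check_compat(model, test_set, "test")
    pred = model.predict(np.ascontiguousarray(test_set.data), batch_size=64)
    cm = confusion_matrix(test_set.labels, pred, model.n_classes)
    report = metrics_from_cm(cm, pe_mode=pe_mode, class_names=list(test_set.class_names) or None)
    return pred, report
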