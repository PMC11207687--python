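"""CNN-LSTM classification of motion-sickness state from PLV matrices.

The modelling surface follows the Model/Results idiom: build a
:class:`VIMSClassifier` from a :class:`~vimsplv.connectivity.ConnectivityDataset`
(or raw arrays), call :meth:`~VIMSClassifier.fit` for a single train/validation
split or :meth:`~VIMSClassifier.cross_validate` for the full 5-fold protocol,
and read estimates, curves and confusion matrices off the returned results
objects.

Training uses Adam (lr 1e-3), cross-entropy loss, batches of 32, at most 50
epochs and early stopping once validation loss has not improved for 10
consecutive epochs; the weights with the best validation loss are kept.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import GroupKFold, StratifiedKFold

from .connectivity import ConnectivityDataset
from .evaluation import EvalReport, mean_confusion
from .nn import Adam, CNNLSTMNet, softmax_cross_entropy

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "EarlyStopping",
    "train_fold",
    "cross_validate",
    "VIMSClassifier",
    "FitResult",
    "CrossValidationResult",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults follow the published model)."""

    input_size: int = 52
    conv1_channels: int = 64
    conv2_channels: int = 128
    kernel: int = 3
    stride: int = 1
    padding: int = 1
    pool: int = 2
    dropout1: float = 0.5
    dropout2: float = 0.3
    lstm1_hidden: int = 100
    lstm2_hidden: int = 50
    n_classes: int = 3

    def __post_init__(self):
        sizes = (self.input_size, self.conv1_channels, self.conv2_channels,
                 self.kernel, self.pool, self.lstm1_hidden, self.lstm2_hidden)
        if any(s <= 0 for s in sizes):
            raise ValueError("all sizes must be positive")
        if not (0 <= self.dropout1 < 1 and 0 <= self.dropout2 < 1):
            raise ValueError("dropout rates must lie in [0, 1)")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        if self.stride != 1 or self.padding != self.kernel // 2:
            raise ValueError("only stride 1 with 'same' padding is supported")

    def build(self, rng: np.random.Generator, dtype=np.float32) -> CNNLSTMNet:
        return CNNLSTMNet(
            input_size=self.input_size,
            n_classes=self.n_classes,
            conv1_channels=self.conv1_channels,
            conv2_channels=self.conv2_channels,
            kernel=self.kernel,
            pool=self.pool,
            dropout1=self.dropout1,
            dropout2=self.dropout2,
            lstm1_hidden=self.lstm1_hidden,
            lstm2_hidden=self.lstm2_hidden,
            rng=rng,
            dtype=dtype,
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam + cross-entropy throughout)."""

    learning_rate: float = 1e-3
    max_epochs: int = 50
    batch_size: int = 32
    early_stop_patience: int = 10
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if not self.early_stop_patience < self.max_epochs:
            raise ValueError("early-stop patience must be < max_epochs")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")


class EarlyStopping:
    """Stop when the monitored loss has not improved for ``patience``
    consecutive epochs; remembers the best epoch."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, loss: float, epoch: int) -> bool:
        """Record this epoch's loss; return True if training should stop."""
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


def _evaluate(net: CNNLSTMNet, x: np.ndarray, y: np.ndarray,
              batch_size: int = 256) -> "tuple[float, float, np.ndarray]":
    """Loss, accuracy and predictions in evaluation mode."""
    losses, preds = [], []
    for i in range(0, x.shape[0], batch_size):
        logits = net.forward(x[i:i + batch_size], train=False)
        loss, _, probs = softmax_cross_entropy(logits, y[i:i + batch_size])
        losses.append(loss * logits.shape[0])
        preds.append(probs.argmax(axis=-1))
    preds = np.concatenate(preds)
    return float(np.sum(losses) / x.shape[0]), float((preds == y).mean()), preds


def train_fold(
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    train_set: "tuple[np.ndarray, np.ndarray]",
    val_set: "tuple[np.ndarray, np.ndarray]",
    rng: "np.random.Generator | None" = None,
):
    """Train one model on one train/validation split.

    Returns ``(net, curves)`` where ``curves`` maps
    train_loss/train_acc/val_loss/val_acc to per-epoch lists.  The returned
    network carries the weights of the epoch with the best validation loss.
    """
    x_tr, y_tr = train_set
    x_val, y_val = val_set
    x_tr = np.asarray(x_tr, dtype=np.float32)
    x_val = np.asarray(x_val, dtype=np.float32)
    y_tr = np.asarray(y_tr)
    y_val = np.asarray(y_val)
    if x_tr.shape[0] == 0 or x_val.shape[0] == 0:
        raise ValueError("train and validation sets must be non-empty")
    if y_tr.min() < 0 or y_tr.max() >= model_cfg.n_classes:
        raise ValueError("labels must lie in {0..n_classes-1}")
    present = set(np.unique(y_tr))
    missing = set(range(model_cfg.n_classes)) - present
    if missing:
        warnings.warn(f"classes {sorted(missing)} absent from the training set")

    rng = rng or np.random.default_rng(train_cfg.seed)
    net = model_cfg.build(rng)
    opt = Adam([ly for ly in net.layers if ly.params()], lr=train_cfg.learning_rate)
    stopper = EarlyStopping(train_cfg.early_stop_patience)
    curves = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_state = net.state_dict()

    n = x_tr.shape[0]
    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, n, train_cfg.batch_size):
            idx = order[i:i + train_cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            logits = net.forward(xb, train=True)
            loss, dlogits, probs = softmax_cross_entropy(logits, yb)
            net.backward(dlogits.astype(net.dtype))
            opt.step()
            ep_loss += loss * len(idx)
            ep_correct += int((probs.argmax(axis=-1) == yb).sum())
        val_loss, val_acc, _ = _evaluate(net, x_val, y_val)
        curves["train_loss"].append(ep_loss / n)
        curves["train_acc"].append(ep_correct / n)
        curves["val_loss"].append(val_loss)
        curves["val_acc"].append(val_acc)
        if val_loss <= stopper.best:
            best_state = net.state_dict()
        if stopper.update(val_loss, epoch):
            break
    net.load_state_dict(best_state)
    return net, curves


def _fold_indices(y, subjects, train_cfg: TrainConfig, split_by: str):
    if split_by == "segment":
        splitter = StratifiedKFold(
            n_splits=train_cfg.folds, shuffle=True, random_state=train_cfg.seed
        )
        return list(splitter.split(np.zeros_like(y), y))
    if split_by == "subject":
        if subjects is None:
            raise ValueError("subject-wise splitting needs subject ids")
        splitter = GroupKFold(n_splits=train_cfg.folds)
        return list(splitter.split(np.zeros_like(y), y, groups=subjects))
    raise ValueError("split_by must be 'segment' or 'subject'")


def cross_validate(
    x: np.ndarray,
    y: np.ndarray,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    subjects: "np.ndarray | None" = None,
    split_by: str = "segment",
) -> "CrossValidationResult":
    """K-fold cross-validation (default 5 folds, stratified by class).

    Every sample lands in exactly one test fold.  ``split_by='subject'``
    keeps all segments of a subject in the same fold, avoiding the identity
    leakage inherent to segment-level splitting.
    """
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y)
    reports, nets = [], []
    for fold, (tr_idx, te_idx) in enumerate(
        _fold_indices(y, subjects, train_cfg, split_by)
    ):
        rng = np.random.default_rng(
            np.random.SeedSequence([train_cfg.seed, fold])
        )
        net, curves = train_fold(
            model_cfg, train_cfg, (x[tr_idx], y[tr_idx]), (x[te_idx], y[te_idx]),
            rng=rng,
        )
        _, _, preds = _evaluate(net, x[te_idx], y[te_idx])
        reports.append(
            EvalReport.from_predictions(y[te_idx], preds, model_cfg.n_classes,
                                        curves=curves)
        )
        nets.append(net)
    return CrossValidationResult(
        fold_reports=reports,
        nets=nets,
        model_config=model_cfg,
        train_config=train_cfg,
        split_by=split_by,
    )


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class VIMSClassifier:
    """CNN-LSTM motion-sickness classifier over PLV connectivity matrices.

    Parameters
    ----------
    x : (n, 52, 52) array of PLV matrices (values already in [0, 1]; fed raw).
    y : integer class labels; ternary keeps the three states, binary merges
        the two sickness grades against rest.
    """

    def __init__(self, x, y, subjects=None,
                 model_config: "ModelConfig | None" = None,
                 train_config: "TrainConfig | None" = None):
        self.x = np.asarray(x, dtype=np.float32)
        self.y = np.asarray(y)
        self.subjects = None if subjects is None else np.asarray(subjects)
        n_classes = int(self.y.max()) + 1 if model_config is None else model_config.n_classes
        self.model_config = model_config or ModelConfig(n_classes=max(2, n_classes))
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_dataset(cls, dataset: ConnectivityDataset, n_classes: int = 3,
                     model_config: "ModelConfig | None" = None,
                     train_config: "TrainConfig | None" = None) -> "VIMSClassifier":
        y = dataset.class_labels(n_classes)
        if model_config is None:
            model_config = ModelConfig(
                input_size=dataset.matrices.shape[1], n_classes=n_classes
            )
        return cls(dataset.matrices, y, subjects=dataset.subjects,
                   model_config=model_config, train_config=train_config)

    def fit(self, val_fraction: float = 0.2) -> "FitResult":
        """Train on a single stratified train/validation split."""
        cfg = self.train_config
        rng = np.random.default_rng(cfg.seed)
        order = rng.permutation(len(self.y))
        # stratified holdout: round-robin within each class
        val_idx = []
        for cls_ in np.unique(self.y):
            members = order[np.isin(order, np.flatnonzero(self.y == cls_))]
            k = max(1, int(round(val_fraction * members.size)))
            val_idx.extend(members[:k])
        val_mask = np.zeros(len(self.y), dtype=bool)
        val_mask[val_idx] = True
        net, curves = train_fold(
            self.model_config, cfg,
            (self.x[~val_mask], self.y[~val_mask]),
            (self.x[val_mask], self.y[val_mask]),
            rng=rng,
        )
        _, _, preds = _evaluate(net, self.x[val_mask], self.y[val_mask])
        report = EvalReport.from_predictions(
            self.y[val_mask], preds, self.model_config.n_classes, curves=curves
        )
        return FitResult(net=net, report=report, model=self)

    def cross_validate(self, split_by: str = "segment") -> "CrossValidationResult":
        """The full k-fold protocol (default: 5 stratified segment-level folds)."""
        return cross_validate(self.x, self.y, self.model_config,
                              self.train_config, subjects=self.subjects,
                              split_by=split_by)


@dataclass
class FitResult:
    """A trained network plus its validation report and training curves."""

    net: CNNLSTMNet
    report: EvalReport
    model: VIMSClassifier

    @property
    def accuracy(self) -> float:
        return self.report.accuracy

    def predict(self, x) -> np.ndarray:
        return self.net.predict(x)

    def predict_proba(self, x) -> np.ndarray:
        return self.net.predict_proba(x)

    def summary(self) -> str:
        r = self.report
        lines = [
            "CNN-LSTM fit (single validation split)",
            "=" * 46,
            f"validation accuracy       {r.accuracy:8.4f}",
            f"validation samples        {r.n_samples:8d}",
            f"epochs run                {len(r.curves.get('val_loss', [])):8d}",
        ]
        for k, rec in enumerate(r.recalls):
            lines.append(f"recall class {k}            {rec:8.4f}")
        return "\n".join(lines)


@dataclass
class CrossValidationResult:
    """Per-fold reports plus cross-fold aggregates."""

    fold_reports: list
    nets: list
    model_config: ModelConfig
    train_config: TrainConfig
    split_by: str = "segment"

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.fold_reports])

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def std_accuracy(self) -> float:
        return float(self.fold_accuracies.std(ddof=1))

    @property
    def mean_confusion(self) -> np.ndarray:
        """Element-wise mean of the per-fold row-normalized confusion
        matrices (the 'average confusion matrix')."""
        return mean_confusion(self.fold_reports)

    def summary(self) -> str:
        accs = self.fold_accuracies
        lines = [
            f"CNN-LSTM {len(accs)}-fold cross-validation "
            f"({self.model_config.n_classes}-class, split by {self.split_by})",
            "=" * 56,
            "fold   accuracy",
        ]
        lines += [f"{i:4d}   {a:.4f}" for i, a in enumerate(accs)]
        lines.append("-" * 56)
        lines.append(f"mean   {self.mean_accuracy:.4f}  +/- {self.std_accuracy:.4f} (sd)")
        lines.append("mean confusion (rows = true, cols = predicted):")
        for row in self.mean_confusion:
            lines.append("   " + "  ".join(f"{v:.3f}" for v in row))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_classes": self.model_config.n_classes,
            "split_by": self.split_by,
            "seed": self.train_config.seed,
            "fold_accuracies": self.fold_accuracies.tolist(),
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "mean_confusion": self.mean_confusion.tolist(),
            "folds": [r.to_dict() for r in self.fold_reports],
        }

    def save(self, out_dir: "str | Path", prefix: str = "cv") -> None:
        """Fold reports as JSON + CSV curves; checkpoints as npz."""
        import json

        import pandas as pd

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{prefix}_report.json").write_text(json.dumps(self.to_dict(), indent=2))
        for i, r in enumerate(self.fold_reports):
            if r.curves:
                pd.DataFrame(r.curves).to_csv(out / f"{prefix}_fold{i}_curves.csv",
                                              index_label="epoch")
        for i, net in enumerate(self.nets):
            net.save(out / f"{prefix}_fold{i}_weights.npz")
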