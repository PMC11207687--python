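"""Classification metrics: accuracy, per-class recall and row-normalized
confusion matrices.

Accuracy is the fraction of correctly predicted samples (the binary
(TP+TN)/(TP+FN+FP+TN) generalized to any number of classes); recall for a
class is TP/(TP+FN).  Confusion matrices have true classes on rows and
predicted classes on columns, each non-empty row normalized to sum to 1, so
the diagonal holds the per-class recalls.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "accuracy",
    "recall",
    "confusion_counts",
    "confusion_normalized",
    "class_counts",
    "EvalReport",
]


def _check(true_labels, pred_labels):
    t = np.asarray(true_labels).ravel()
    p = np.asarray(pred_labels).ravel()
    if t.size != p.size:
        raise ValueError("label arrays must have equal length")
    if t.size == 0:
        raise ValueError("need at least one sample")
    return t, p


def accuracy(true_labels, pred_labels) -> float:
    """Fraction of samples predicted correctly."""
    t, p = _check(true_labels, pred_labels)
    return float((t == p).mean())


def recall(true_labels, pred_labels, cls) -> float:
    """TP / (TP + FN) for one class; NaN (with a warning) if the class has
    no true members."""
    t, p = _check(true_labels, pred_labels)
    mask = t == cls
    if not mask.any():
        warnings.warn(f"recall undefined: no true samples of class {cls}")
        return float("nan")
    return float((p[mask] == cls).mean())


def confusion_counts(true_labels, pred_labels, n_classes: int) -> np.ndarray:
    """Raw confusion counts, rows = true class, columns = predicted."""
    t, p = _check(true_labels, pred_labels)
    return _sk_confusion(t, p, labels=np.arange(n_classes))


def confusion_normalized(true_labels, pred_labels, n_classes: int) -> np.ndarray:
    """Row-normalized confusion matrix; an empty row stays all-zero."""
    counts = confusion_counts(true_labels, pred_labels, n_classes).astype(float)
    sums = counts.sum(axis=1, keepdims=True)
    return np.divide(counts, sums, out=np.zeros_like(counts), where=sums > 0)


def class_counts(true_labels, pred_labels, n_classes: int) -> "dict[int, dict[str, int]]":
    """One-vs-rest TP/FP/TN/FN per class."""
    cm = confusion_counts(true_labels, pred_labels, n_classes)
    total = cm.sum()
    out = {}
    for k in range(n_classes):
        tp = int(cm[k, k])
        fn = int(cm[k].sum() - tp)
        fp = int(cm[:, k].sum() - tp)
        out[k] = {"TP": tp, "FP": fp, "FN": fn, "TN": int(total - tp - fn - fp)}
    return out


@dataclass
class EvalReport:
    """Evaluation of one model on one test set, plus its training curves."""

    accuracy: float
    recalls: np.ndarray
    confusion: np.ndarray           # row-normalized
    counts: dict                    # per-class TP/FP/TN/FN
    n_samples: int
    curves: dict = field(default_factory=dict)  # per-epoch train/val loss+acc

    @classmethod
    def from_predictions(cls, true_labels, pred_labels, n_classes: int,
                         curves: "dict | None" = None) -> "EvalReport":
        t, p = _check(true_labels, pred_labels)
        conf = confusion_normalized(t, p, n_classes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            recs = np.array([recall(t, p, k) for k in range(n_classes)])
        return cls(
            accuracy=accuracy(t, p),
            recalls=recs,
            confusion=conf,
            counts=class_counts(t, p, n_classes),
            n_samples=t.size,
            curves=dict(curves or {}),
        )

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recalls": [None if np.isnan(r) else float(r) for r in self.recalls],
            "confusion": self.confusion.tolist(),
            "counts": self.counts,
            "n_samples": self.n_samples,
            "curves": {k: list(map(float, v)) for k, v in self.curves.items()},
        }

    def save_json(self, path: "str | Path") -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def save_confusion_csv(self, path: "str | Path") -> None:
        import pandas as pd

        n = self.confusion.shape[0]
        names = [f"VIMS_{k}" for k in range(n)] if n == 3 else ["rest", "sick"][:n]
        pd.DataFrame(self.confusion, index=names, columns=names).to_csv(path)

    def plot_confusion(self, ax=None):
        """Heat-map rendering of the normalized confusion matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.confusion, vmin=0, vmax=1, cmap="Blues")
        n = self.confusion.shape[0]
        for i in range(n):
            for j in range(n):
                ax.text(j, i, f"{self.confusion[i, j]:.2f}",
                        ha="center", va="center")
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.figure.colorbar(im, ax=ax)
        return ax


def mean_confusion(reports: Sequence[EvalReport]) -> np.ndarray:
    """Element-wise mean of per-fold row-normalized confusion matrices."""
    return np.mean([r.confusion for r in reports], axis=0)
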