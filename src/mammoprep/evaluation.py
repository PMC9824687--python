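"""Confusion-matrix bookkeeping and accuracy scoring.

The headline score here is (TP + TN) / (TP + TN + FP + FN) — the fraction
of correctly classified items.  In parts of the mammography CAD
literature this quantity is reported under the name "precision"; to avoid
ambiguity this module calls it accuracy and additionally reports the
standard precision TP/(TP+FP), recall TP/(TP+FN) and f1 per class, plus
support.  Rows of the confusion matrix are true classes, columns are
predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "build_confusion", "accuracy_eq1", "error_rate", "per_class_report"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts: rows = true class, columns = predicted class."""

    classes: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise ValueError("counts must be K x K for K classes")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, positive) -> tuple[int, int, int, int]:
        """Collapse to (TP, TN, FP, FN) for one class against the rest."""
        i = self.classes.index(positive)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum()) - tp
        fp = int(self.counts[:, i].sum()) - tp
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn

    def to_csv(self, path: Union[str, Path]) -> None:
        names = [getattr(c, "value", c) for c in self.classes]
        pd.DataFrame(self.counts, index=names, columns=names).to_csv(Path(path))


def build_confusion(
    true_labels: Sequence, pred_labels: Sequence, classes: Sequence
) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a confusion matrix."""
    if len(true_labels) != len(pred_labels):
        raise ValueError("true and predicted label sequences must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(true_labels, pred_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown label: {t if t not in index else p}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(tuple(classes), counts)


def accuracy_eq1(cm: ConfusionMatrix, positive_class=None) -> float:
    """(TP + TN) / (TP + TN + FP + FN).

    With ``positive_class`` the matrix is collapsed one-vs-rest first;
    without it the multiclass overall value trace/total is returned, which
    coincides with the binary form for K = 2.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if positive_class is not None:
        tp, tn, fp, fn = cm.one_vs_rest(positive_class)
        return (tp + tn) / (tp + tn + fp + fn)
    return float(np.trace(cm.counts)) / cm.total


def error_rate(cm: ConfusionMatrix) -> float:
    """1 - overall accuracy (the "Error" row convention)."""
    return 1.0 - accuracy_eq1(cm)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: 0/0 encountered, reporting 0", stacklevel=3)
        return 0.0
    return num / den


def per_class_report(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class scores plus overall accuracy and error.

    Columns: accuracy (one-vs-rest), precision, recall, f1, support.  The
    overall accuracy and error appear as extra rows ``__overall__`` and
    ``__error__``.  0/0 scores are reported as 0 with a warning.
    """
    rows = {}
    for c in cm.classes:
        tp, tn, fp, fn = cm.one_vs_rest(c)
        name = getattr(c, "value", c)
        precision = _safe_div(tp, tp + fp, f"precision[{name}]")
        recall = _safe_div(tp, tp + fn, f"recall[{name}]")
        f1 = _safe_div(2 * precision * recall, precision + recall, f"f1[{name}]")
        rows[name] = {
            "accuracy": (tp + tn) / cm.total,
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": tp + fn,
        }
    overall = accuracy_eq1(cm)
    rows["__overall__"] = {
        "accuracy": overall,
        "precision": np.nan,
        "recall": np.nan,
        "f1": np.nan,
        "support": cm.total,
    }
    rows["__error__"] = {
        "accuracy": 1.0 - overall,
        "precision": np.nan,
        "recall": np.nan,
        "f1": np.nan,
        "support": cm.total,
    }
    return pd.DataFrame.from_dict(rows, orient="index")
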