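"""Confusion-matrix evaluation: per-class recall, PPV, and F1.

Conventions: rows of the confusion matrix are the gold-standard class,
columns the automated classification.  Recall is the diagonal over the
row total, PPV (positive predictive value, i.e. precision) the diagonal
over the column total, and F1 the harmonic mean of the *unrounded*
recall and PPV.  The macro F1 is the unweighted mean of per-class F1.

Reported values are truncated — not rounded — to two decimals (e.g. a
PPV of 0.5688 is reported as 0.56); full-precision values are always
retained alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import sklearn.metrics as _skm

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "confusion_matrix",
    "class_metrics",
    "macro_f1",
    "truncate2",
]


def truncate2(value: float) -> float:
    """Truncate (floor) to two decimals, the reporting convention."""
    return float(np.floor(value * 100.0 + 1e-12) / 100.0)


@dataclass
class ConfusionMatrix:
    """K x K counts: gold-standard rows vs automated-classification columns."""

    counts: np.ndarray
    class_order: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if self.counts.shape[0] != len(self.class_order):
            raise ValueError("class_order length must match matrix size")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def n_items(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassMetrics:
    """Per-class and macro recall/PPV/F1, full precision and truncated."""

    class_order: tuple
    recall: np.ndarray
    ppv: np.ndarray
    f1: np.ndarray
    macro_recall: float
    macro_ppv: float
    macro_f1: float

    def truncated(self) -> dict:
        """The two-decimal truncated report, keyed by class name."""
        report = {
            str(label): {
                "recall": truncate2(self.recall[i]),
                "ppv": truncate2(self.ppv[i]),
                "f1": truncate2(self.f1[i]),
            }
            for i, label in enumerate(self.class_order)
        }
        report["macro"] = {
            "recall": truncate2(self.macro_recall),
            "ppv": truncate2(self.macro_ppv),
            "f1": truncate2(self.macro_f1),
        }
        return report


def confusion_matrix(
    gold: Sequence, predicted: Sequence, class_order: Sequence
) -> ConfusionMatrix:
    """Count gold-vs-predicted labels in the given class order."""
    if len(gold) != len(predicted):
        raise ValueError("gold and predicted label sequences differ in length")
    class_order = tuple(class_order)
    known = set(class_order)
    for lab in list(gold) + list(predicted):
        if lab not in known:
            raise ValueError(f"label {lab!r} not in class order")
    counts = _skm.confusion_matrix(
        list(gold), list(predicted), labels=list(class_order)
    )
    return ConfusionMatrix(counts, class_order)


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Recall/PPV/F1 per class plus unweighted macro averages.

    Raises when a gold class has no items (recall undefined) or a
    predicted column is empty (PPV undefined).
    """
    counts = cm.counts.astype(np.float64)
    row_totals = counts.sum(axis=1)
    col_totals = counts.sum(axis=0)
    for i, label in enumerate(cm.class_order):
        if row_totals[i] == 0:
            raise ValueError(f"recall undefined: gold class {label} has no items")
        if col_totals[i] == 0:
            raise ValueError(f"ppv undefined: no predictions for class {label}")
    diag = np.diag(counts)
    recall = diag / row_totals
    ppv = diag / col_totals
    with np.errstate(invalid="ignore"):
        f1 = np.where(recall + ppv > 0, 2 * recall * ppv / (recall + ppv), 0.0)
    return ClassMetrics(
        class_order=cm.class_order,
        recall=recall,
        ppv=ppv,
        f1=f1,
        macro_recall=float(recall.mean()),
        macro_ppv=float(ppv.mean()),
        macro_f1=float(f1.mean()),
    )


def macro_f1(cm: ConfusionMatrix) -> float:
    """Unweighted mean of unrounded per-class F1 (full precision)."""
    return class_metrics(cm).macro_f1
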