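"""Confusion-matrix bookkeeping and the four classification metrics.

The positive class is the tumor-cell-cluster (CTCC) event; the negative
class is the non-cluster (NC) scattering event. All metrics are returned
as percentages in [0, 100]:

    purity      = TP / (TP + FP) * 100      (precision)
    sensitivity = TP / (TP + FN) * 100      (recall)
    specificity = TN / (TN + FP) * 100
    accuracy    = (TP + TN) / (TP + TN + FP + FN) * 100

A metric whose denominator is zero is undefined; it is reported as
``math.nan`` with a warning rather than a silent zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion",
    "purity",
    "sensitivity",
    "specificity",
    "accuracy",
    "all_metrics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred, positive=1) -> ConfusionCounts:
    """Tally a binary confusion matrix.

    ``y_true`` and ``y_pred`` are equal-length label sequences; any label
    equal to ``positive`` counts as the positive (CTCC) class.
    """
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape:
        raise ValueError(f"label length mismatch: {t.shape} vs {p.shape}")
    tpos = t == positive
    ppos = p == positive
    return ConfusionCounts(
        tp=int(np.sum(tpos & ppos)),
        fp=int(np.sum(~tpos & ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
        fn=int(np.sum(tpos & ~ppos)),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator", stacklevel=3)
        return math.nan
    return 100.0 * num / den


def purity(c: ConfusionCounts) -> float:
    """Fraction of predicted clusters that are true clusters (%)."""
    return _ratio(c.tp, c.tp + c.fp, "purity")


def sensitivity(c: ConfusionCounts) -> float:
    """Fraction of true clusters predicted as clusters (%)."""
    return _ratio(c.tp, c.tp + c.fn, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    """Fraction of true non-clusters predicted as non-clusters (%)."""
    return _ratio(c.tn, c.tn + c.fp, "specificity")


def accuracy(c: ConfusionCounts) -> float:
    """Fraction of all events classified correctly (%)."""
    return _ratio(c.tp + c.tn, c.total, "accuracy")


def all_metrics(c: ConfusionCounts) -> dict[str, float]:
    return {
        "purity": purity(c),
        "sensitivity": sensitivity(c),
        "specificity": specificity(c),
        "accuracy": accuracy(c),
    }
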