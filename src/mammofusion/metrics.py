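"""Binary-classification evaluation: confusion counting and derived metrics.

The positive class is *malignant* (label 1).  The five standard diagnostic
metrics are computed from the confusion counts:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)        (sensitivity)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * recall / (precision + recall)

A metric with a zero denominator is reported as the explicit ``None``
(undefined) marker rather than 0 or an exception.  Metrics are fractions in
[0, 1]; multiply by 100 only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InvalidInputError

__all__ = ["ConfusionCounts", "MetricSet", "confusion", "compute_metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN cell counts of the 2x2 cross-tabulation."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise InvalidInputError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_table(self) -> str:
        """2x2 text table, rows = true class, columns = predicted class."""
        w = max(len(str(v)) for v in (self.tp, self.tn, self.fp, self.fn))
        w = max(w, 6)
        return "\n".join(
            [
                f"{'':>12} {'pred benign':>{w + 6}} {'pred malignant':>{w + 9}}",
                f"{'benign':>12} {self.tn:>{w + 6}} {self.fp:>{w + 9}}",
                f"{'malignant':>12} {self.fn:>{w + 6}} {self.tp:>{w + 9}}",
            ]
        )


@dataclass(frozen=True)
class MetricSet:
    """The five diagnostic metrics; ``None`` marks an undefined value."""

    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    specificity: Optional[float]
    f1: Optional[float]

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
        }


def confusion(labels, predictions) -> ConfusionCounts:
    """Cross-tabulate binary truth labels against binary predictions."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape or y.ndim != 1:
        raise InvalidInputError(
            f"labels and predictions must be equal-length 1-D vectors, "
            f"got shapes {y.shape} and {p.shape}"
        )
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise InvalidInputError("labels and predictions must be binary (0/1)")
    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def compute_metrics(cc: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, recall, specificity and F1 from confusion counts."""
    if cc.total == 0:
        raise InvalidInputError("cannot compute metrics from zero evaluated samples")
    precision = _ratio(cc.tp, cc.tp + cc.fp)
    recall = _ratio(cc.tp, cc.tp + cc.fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricSet(
        accuracy=_ratio(cc.tp + cc.tn, cc.total),
        precision=precision,
        recall=recall,
        specificity=_ratio(cc.tn, cc.tn + cc.fp),
        f1=f1,
    )
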