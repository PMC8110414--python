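"""Confusion matrix, overall accuracy and per-class sensitivity /
precision for the five AAMI classes.

Two reporting conventions are provided because published confusion
tables are not always consistent with their own axis labels:

``standard``
    sensitivity (recall) ``Se_c = diag_c / row-sum_c`` and precision
    (positive predictive value) ``P+_c = diag_c / column-sum_c``,
    with rows = actual class and columns = predicted class;
``paper_table``
    the transposed assignment, ``Se_c = diag_c / column-sum_c`` and
    ``P+_c = diag_c / row-sum_c``.  Some published tables are only
    internally consistent under this reading, so it is kept for
    auditing printed results.

Degenerate 0/0 ratios are reported as 0 and percentages are rounded
half-up to two decimals, matching the usual table formatting.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .record_io import AamiClass

__all__ = [
    "ConfusionMatrix5",
    "ClassMetrics",
    "confusion_matrix",
    "overall_accuracy",
    "per_class_metrics",
    "round_half_up",
]

N_CLASSES = len(AamiClass)


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), as used in printed
    percentage tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix5:
    """5x5 count matrix; rows = actual class, columns = predicted
    class, both in the order N, V, S, F, Q."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"confusion matrix must be {N_CLASSES}x{N_CLASSES}")
        if (counts < 0).any():
            raise ValueError("confusion-matrix counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def diagonal(self) -> np.ndarray:
        return np.diagonal(self.counts)

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def transposed(self) -> "ConfusionMatrix5":
        return ConfusionMatrix5(self.counts.T.copy())


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class sensitivity and precision (percent, two decimals)
    plus overall accuracy, under a stated convention."""

    sensitivity: dict[str, float]
    precision: dict[str, float]
    accuracy: float
    convention: str


def confusion_matrix(
    true_labels: Sequence[AamiClass | int],
    predicted_labels: Sequence[AamiClass | int],
) -> ConfusionMatrix5:
    """Count (actual, predicted) pairs into a 5x5 matrix."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences differ in length")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        counts[AamiClass(t).value, AamiClass(p).value] += 1
    return ConfusionMatrix5(counts)


def overall_accuracy(cm: ConfusionMatrix5) -> float:
    """100 * trace / total."""
    if cm.total == 0:
        raise ValueError("cannot compute accuracy of an empty confusion matrix")
    return 100.0 * float(cm.diagonal.sum()) / cm.total


def _safe_ratio(num: float, den: float) -> float:
    return 0.0 if den == 0 else 100.0 * num / den


def per_class_metrics(
    cm: ConfusionMatrix5, convention: str = "standard"
) -> ClassMetrics:
    """Sensitivity and precision per class under the given convention.

    ``standard`` divides the diagonal by row totals for Se and column
    totals for P+; ``paper_table`` swaps the two denominators.  The
    two conventions are exact transposes of one another.
    """
    if convention not in ("standard", "paper_table"):
        raise ValueError(f"unknown convention {convention!r}")
    rows = cm.row_totals()
    cols = cm.column_totals()
    diag = cm.diagonal
    se_den, pp_den = (rows, cols) if convention == "standard" else (cols, rows)
    sensitivity = {
        c.name: round_half_up(_safe_ratio(diag[c.value], se_den[c.value]))
        for c in AamiClass
    }
    precision = {
        c.name: round_half_up(_safe_ratio(diag[c.value], pp_den[c.value]))
        for c in AamiClass
    }
    return ClassMetrics(
        sensitivity=sensitivity,
        precision=precision,
        accuracy=round_half_up(overall_accuracy(cm)),
        convention=convention,
    )
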