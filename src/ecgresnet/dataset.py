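"""Interpatient dataset assembly.

The interpatient protocol keeps every patient record entirely inside
one of the training / validation / test sets, so the classifier is
never evaluated on beats from a patient it saw during training.  The
default split is the published 44-record arrangement of the MIT-BIH
arrhythmia database: 11 training records, 11 validation records and
22 test records (the three paced records 102, 104 and 107 are simply
absent from the lists).

Labels are one-hot encoded in the fixed class order N, V, S, F, Q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .record_io import AamiClass
from .slicer import Slice

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec",
    "LabeledDataset",
    "interpatient_split",
    "encode_labels",
    "decode_labels",
    "swap_cross_validation",
]

DEFAULT_TRAIN_RECORDS = (
    "124", "201", "203", "205", "207", "208", "209", "215", "220", "223", "230",
)
DEFAULT_VALIDATION_RECORDS = (
    "101", "106", "108", "109", "112", "114", "115", "116", "118", "119", "122",
)
DEFAULT_TEST_RECORDS = (
    "100", "103", "105", "111", "113", "117", "121", "123", "200", "202",
    "210", "212", "213", "214", "219", "221", "222", "228", "231", "232",
    "233", "234",
)


@dataclass(frozen=True)
class SplitSpec:
    """Record-level assignment of patients to the three sets."""

    train_records: tuple[str, ...] = DEFAULT_TRAIN_RECORDS
    validation_records: tuple[str, ...] = DEFAULT_VALIDATION_RECORDS
    test_records: tuple[str, ...] = DEFAULT_TEST_RECORDS

    def __post_init__(self) -> None:
        object.__setattr__(self, "train_records", tuple(map(str, self.train_records)))
        object.__setattr__(
            self, "validation_records", tuple(map(str, self.validation_records))
        )
        object.__setattr__(self, "test_records", tuple(map(str, self.test_records)))
        sets = [
            set(self.train_records),
            set(self.validation_records),
            set(self.test_records),
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(
                        f"records {sorted(overlap)} appear in more than one set"
                    )

    @property
    def all_records(self) -> set[str]:
        return (
            set(self.train_records)
            | set(self.validation_records)
            | set(self.test_records)
        )


@dataclass
class LabeledDataset:
    """Slice windows with one-hot labels.

    ``X`` has shape ``(n, window)`` (mV, optionally z-scored per
    slice), ``y`` shape ``(n, 5)`` with exactly one 1 per row in class
    order N, V, S, F, Q.
    """

    X: np.ndarray
    y: np.ndarray
    record_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if len(self.X) != len(self.y):
            raise ValueError("X and y must have the same number of rows")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def labels(self) -> list[AamiClass]:
        return decode_labels(self.y)

    def class_counts(self) -> dict[str, int]:
        counts = self.y.sum(axis=0).astype(int) if len(self) else np.zeros(5, int)
        return {c.name: int(counts[c.value]) for c in AamiClass}


def encode_labels(labels: Sequence[AamiClass]) -> np.ndarray:
    """One-hot encode AAMI labels (n x 5, column order N,V,S,F,Q)."""
    y = np.zeros((len(labels), len(AamiClass)))
    for i, lab in enumerate(labels):
        y[i, AamiClass(lab).value] = 1.0
    return y


def decode_labels(onehot: np.ndarray) -> list[AamiClass]:
    """Inverse of :func:`encode_labels`."""
    onehot = np.asarray(onehot)
    if onehot.ndim != 2 or onehot.shape[1] != len(AamiClass):
        raise ValueError("one-hot matrix must be n x 5")
    return [AamiClass(int(i)) for i in onehot.argmax(axis=1)]


def normalize_slices(X: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Per-slice z-scoring: each window is centred and scaled to unit
    standard deviation (flat windows are centred only)."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    return (X - mu) / np.maximum(sd, eps)


def _assemble(slices: list[Slice], normalize: bool) -> LabeledDataset:
    if not slices:
        return LabeledDataset(
            X=np.zeros((0, 1)), y=np.zeros((0, len(AamiClass))), record_ids=[]
        )
    X = np.stack([s.samples for s in slices])
    if normalize:
        X = normalize_slices(X)
    y = encode_labels([s.label for s in slices])
    return LabeledDataset(X=X, y=y, record_ids=[s.record_id for s in slices])


def interpatient_split(
    slices: Sequence[Slice],
    spec: SplitSpec = SplitSpec(),
    normalize: bool = True,
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Route slices to train/validation/test by their record id.

    Record-level disjointness is guaranteed by ``SplitSpec``; slices
    from records absent from all three lists are excluded with a
    warning.  Per-slice z-scoring is applied by default.
    """
    train_ids = set(spec.train_records)
    val_ids = set(spec.validation_records)
    test_ids = set(spec.test_records)
    buckets: dict[str, list[Slice]] = {"train": [], "val": [], "test": []}
    excluded: set[str] = set()
    for s in slices:
        if s.record_id in train_ids:
            buckets["train"].append(s)
        elif s.record_id in val_ids:
            buckets["val"].append(s)
        elif s.record_id in test_ids:
            buckets["test"].append(s)
        else:
            excluded.add(s.record_id)
    if excluded:
        logger.warning(
            "records %s are not listed in the split and were excluded",
            sorted(excluded),
        )
    out = tuple(_assemble(buckets[k], normalize) for k in ("train", "val", "test"))
    for name, ds in zip(("train", "validation", "test"), out):
        logger.info("%s set: %d slices, classes %s", name, len(ds), ds.class_counts())
    return out


def swap_cross_validation(spec: SplitSpec) -> SplitSpec:
    """Exchange the training and validation record lists (the second
    half-swap of the two-fold cross-validation); the test list is
    untouched."""
    return SplitSpec(
        train_records=spec.validation_records,
        validation_records=spec.train_records,
        test_records=spec.test_records,
    )
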