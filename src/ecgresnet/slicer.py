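"""Cutting records into fixed-length labeled slices.

Classification operates on 3-second windows: 1080 samples at 360 Hz.
Windows start at the beginning of the record and advance by a fixed
stride (540 samples by default, i.e. 50% overlap, which increases the
number of training samples).  A beat belongs to a window when its
annotated R-peak index lies in the half-open interval
``[start, start + window)``.

Each slice receives one AAMI label by four rules:

1. all beats normal -> the slice is N;
2. any non-normal beat present -> the slice is abnormal;
3. among abnormal types, the most represented type wins;
4. on a tie, the abnormal type appearing first in the slice wins.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .record_io import AamiClass, BeatAnnotation, EcgRecord

logger = logging.getLogger(__name__)

__all__ = ["Slice", "SliceConfig", "make_slices", "label_slice"]


@dataclass(frozen=True)
class SliceConfig:
    """Window geometry: 1080-sample windows, 540-sample stride by
    default; slices containing no annotated beat are dropped."""

    window: int = 1080
    stride: int = 540
    drop_empty: bool = True

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be positive")
        if not 1 <= self.stride <= self.window:
            raise ValueError("stride must satisfy 1 <= stride <= window")


@dataclass
class Slice:
    """A labeled window — the unit of classification."""

    samples: np.ndarray
    label: AamiClass | None
    record_id: str
    start_index: int
    beats: list[tuple[int, AamiClass]] = field(default_factory=list)


def label_slice(beats: Sequence[AamiClass]) -> AamiClass:
    """Assign one AAMI class to a window from its beats, in window
    order, by the four labeling rules."""
    if len(beats) == 0:
        raise ValueError("cannot label a slice without beats")
    abnormal = [b for b in beats if b != AamiClass.N]
    if not abnormal:
        return AamiClass.N
    counts = Counter(abnormal)
    top = max(counts.values())
    # first-appearance order breaks ties among the most represented types
    for b in abnormal:
        if counts[b] == top:
            return b
    raise AssertionError("unreachable")


def make_slices(
    record: EcgRecord,
    annotations: Sequence[BeatAnnotation],
    config: SliceConfig = SliceConfig(),
    channel: int = 0,
) -> list[Slice]:
    """Cut one channel of a record into labeled slices.

    Slice ``k`` starts at ``k * stride`` for
    ``k = 0 .. floor((L - window) / stride)``.  Beats are assigned by
    the half-open convention; windows without any beat are dropped
    when ``drop_empty`` (no labeling rule covers them), otherwise kept
    with ``label=None``.
    """
    x = record.channel(channel)
    L = x.size
    if L < config.window:
        logger.warning(
            "record %s (%d samples) is shorter than the %d-sample window",
            record.record_id, L, config.window,
        )
        return []
    idx = np.array([a.sample_index for a in annotations], dtype=int)
    cls = [a.aami_class for a in annotations]
    order = np.argsort(idx, kind="stable")
    idx, cls = idx[order], [cls[i] for i in order]

    out: list[Slice] = []
    n_slices = (L - config.window) // config.stride + 1
    for k in range(n_slices):
        start = k * config.stride
        lo = np.searchsorted(idx, start, side="left")
        hi = np.searchsorted(idx, start + config.window, side="left")
        beats = [(int(idx[i]), cls[i]) for i in range(lo, hi)]
        if not beats and config.drop_empty:
            continue
        label = label_slice([c for _, c in beats]) if beats else None
        out.append(
            Slice(
                samples=x[start : start + config.window].copy(),
                label=label,
                record_id=record.record_id,
                start_index=start,
                beats=beats,
            )
        )
    return out


def slices_to_csv(slices: Sequence[Slice], path) -> None:
    """Write slices as CSV: record_id, start_index, label, then the
    window samples."""
    with open(path, "w") as fh:
        for s in slices:
            label = s.label.name if s.label is not None else ""
            vals = ",".join(f"{v:.6f}" for v in s.samples)
            fh.write(f"{s.record_id},{s.start_index},{label},{vals}\n")
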