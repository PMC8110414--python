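"""Reading and writing ambulatory ECG records and beat annotations.

Two on-disk dialects are supported:

* the PhysioNet conventions used by the MIT-BIH arrhythmia database —
  a text header (``.hea``), format-212 signal packing (two 12-bit
  two's-complement samples in three bytes, ``.dat``) and the binary
  beat-annotation stream (``.atr``);
* a plain-text dialect (same header with format token ``txt``, one
  sample row per line in mV, CSV annotations) so that fixtures and
  intermediate files stay human-readable.

Beat symbols are mapped onto the five-class AAMI taxonomy
(N normal, V ventricular ectopic, S supraventricular ectopic,
F fusion, Q unknown/paced).
"""

from __future__ import annotations

import logging
import struct
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AamiClass",
    "EcgRecord",
    "BeatAnnotation",
    "FormatError",
    "IntegrityError",
    "map_to_aami",
    "read_record",
    "read_annotations",
    "write_record",
    "MIT_TO_AAMI",
    "BEAT_SYMBOLS",
]


class FormatError(ValueError):
    """A file does not follow the expected header/signal conventions."""


class IntegrityError(ValueError):
    """Header and signal file are mutually inconsistent."""


class AamiClass(IntEnum):
    """The five AAMI heartbeat classes, with a fixed 0..4 encoding.

    The ordering N, V, S, F, Q is used everywhere in the package:
    one-hot label columns, confusion-matrix axes and reports.
    """

    N = 0
    V = 1
    S = 2
    F = 3
    Q = 4


#: MIT-BIH beat-type symbol -> AAMI class, for the 15 standard beat types.
MIT_TO_AAMI: dict[str, AamiClass] = {
    # Normal (N): normal, left/right bundle branch block, atrial escape,
    # nodal (junctional) escape.
    "N": AamiClass.N,
    "L": AamiClass.N,
    "R": AamiClass.N,
    "e": AamiClass.N,
    "j": AamiClass.N,
    # Ventricular ectopic (V): premature ventricular contraction,
    # ventricular escape.
    "V": AamiClass.V,
    "E": AamiClass.V,
    # Supraventricular ectopic (S): atrial premature, aberrated atrial
    # premature, nodal premature, supraventricular premature.
    "A": AamiClass.S,
    "a": AamiClass.S,
    "J": AamiClass.S,
    "S": AamiClass.S,
    # Fusion (F): fusion of ventricular and normal beat.
    "F": AamiClass.F,
    # Unknown (Q): paced, fusion of paced and normal, unclassifiable.
    "/": AamiClass.Q,
    "f": AamiClass.Q,
    "Q": AamiClass.Q,
}

BEAT_SYMBOLS = frozenset(MIT_TO_AAMI)

#: Annotation symbols that are not heartbeats (rhythm changes, artifacts,
#: signal-quality flags ...).  These are dropped by read_annotations and
#: rejected by map_to_aami.
NON_BEAT_SYMBOLS = frozenset(
    '~|"+=s*Dp^t[]!x@()uT?'
)

# WFDB annotation type codes <-> symbols (the subset needed here).
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 22: '"', 25: "B", 28: "+", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 37: "x", 38: "f", 41: "r",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def map_to_aami(mit_symbol: str) -> AamiClass:
    """Map a single MIT-BIH beat symbol to its AAMI class.

    The 15 standard beat types map per the AAMI taxonomy; an
    unrecognised *beat* symbol is assigned to Q ("unclassifiable")
    with a logged warning.  Non-beat annotation symbols (rhythm
    labels, artifacts) are rejected: callers must pre-filter.
    """
    if mit_symbol in MIT_TO_AAMI:
        return MIT_TO_AAMI[mit_symbol]
    if mit_symbol in NON_BEAT_SYMBOLS:
        raise ValueError(
            f"{mit_symbol!r} is not a heartbeat annotation; filter non-beat "
            "annotations before mapping"
        )
    logger.warning("unknown beat symbol %r mapped to AAMI class Q", mit_symbol)
    return AamiClass.Q


@dataclass
class EcgRecord:
    """A sampled ECG record.

    Attributes
    ----------
    record_id:
        Record name (e.g. ``"100"`` for MIT-BIH, ``"S003"`` for
        synthetic records).
    fs:
        Sampling frequency in Hz (360 for MIT-BIH and for the
        synthetic generator).
    signal:
        Array of shape ``(n_channels, n_samples)`` holding amplitudes
        in millivolts.
    lead_names:
        One name per channel (``"MLII"``, ``"V5"`` ...).
    """

    record_id: str
    fs: float
    signal: np.ndarray
    lead_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if self.signal.ndim != 2 or self.signal.shape[1] < 1:
            raise ValueError("signal must hold at least one sample per channel")
        if not self.lead_names:
            self.lead_names = [f"ch{i}" for i in range(self.signal.shape[0])]
        if len(self.lead_names) != self.signal.shape[0]:
            raise ValueError("one lead name per channel is required")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def channel(self, index: int = 0) -> np.ndarray:
        """Return one channel as a 1-D mV array (default: channel 0,
        MLII on most MIT-BIH records)."""
        return self.signal[index]


@dataclass(frozen=True)
class BeatAnnotation:
    """One annotated heartbeat: R-peak sample index (0-based), the
    MIT-BIH beat symbol and its AAMI class."""

    sample_index: int
    mit_symbol: str
    aami_class: AamiClass

    @classmethod
    def from_symbol(cls, sample_index: int, mit_symbol: str) -> "BeatAnnotation":
        return cls(int(sample_index), mit_symbol, map_to_aami(mit_symbol))


# ---------------------------------------------------------------------------
# format-212 packing

def pack_212(samples: np.ndarray) -> bytes:
    """Pack a flat sequence of 12-bit two's-complement integers into
    format-212 bytes (two samples per three bytes)."""
    a = np.asarray(samples, dtype=np.int64)
    if a.size and (a.max() > 2047 or a.min() < -2048):
        raise ValueError("format 212 holds 12-bit samples in [-2048, 2047]")
    if a.size % 2:
        a = np.concatenate([a, [0]])
    a = a & 0xFFF
    s0, s1 = a[0::2], a[1::2]
    out = np.empty(3 * s0.size, dtype=np.uint8)
    out[0::3] = s0 & 0xFF
    out[1::3] = ((s0 >> 8) & 0xF) | (((s1 >> 8) & 0xF) << 4)
    out[2::3] = s1 & 0xFF
    return out.tobytes()


def unpack_212(data: bytes, n_samples: int) -> np.ndarray:
    """Inverse of :func:`pack_212`; returns ``n_samples`` signed ints."""
    raw = np.frombuffer(data, dtype=np.uint8)
    if raw.size % 3:
        raw = raw[: raw.size - raw.size % 3]
    b0, b1, b2 = raw[0::3].astype(np.int64), raw[1::3].astype(np.int64), raw[2::3]
    s0 = b0 | ((b1 & 0xF) << 8)
    s1 = b2.astype(np.int64) | ((b1 >> 4) << 8)
    flat = np.empty(2 * s0.size, dtype=np.int64)
    flat[0::2], flat[1::2] = s0, s1
    if flat.size < n_samples:
        raise IntegrityError(
            f"signal file holds {flat.size} samples, header declares {n_samples}"
        )
    flat = flat[:n_samples]
    return np.where(flat >= 2048, flat - 4096, flat)


# ---------------------------------------------------------------------------
# header parsing

@dataclass
class _SignalSpec:
    file_name: str
    fmt: str
    gain: float
    baseline: int
    description: str


def _parse_header(header_path: Path) -> tuple[str, int, float, int, list[_SignalSpec]]:
    lines = [
        ln.strip()
        for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"empty header file {header_path}")
    head = lines[0].split()
    if len(head) < 2:
        raise FormatError(f"malformed header line {lines[0]!r}")
    record_id = head[0].split("/")[0]
    try:
        n_sig = int(head[1])
        fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
        n_samples = int(head[3]) if len(head) > 3 else 0
    except ValueError as exc:
        raise FormatError(f"malformed header line {lines[0]!r}") from exc
    if len(lines) < 1 + n_sig:
        raise FormatError(f"header declares {n_sig} signals but lists fewer")
    specs = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        if len(tok) < 2:
            raise FormatError(f"malformed signal line {ln!r}")
        fmt = tok[1] if tok[1] == "txt" else tok[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline = 200.0, None
        if len(tok) > 2:
            g = tok[2].split("/")[0]
            if "(" in g:
                g, b = g.split("(")
                baseline = int(b.rstrip(")"))
            gain = float(g) if float(g) != 0 else 200.0
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(tok[8:]) if len(tok) > 8 else f"ch{len(specs)}"
        specs.append(_SignalSpec(tok[0], fmt, gain, baseline, desc))
    return record_id, n_sig, fs, n_samples, specs


def read_record(header_path: str | Path) -> EcgRecord:
    """Read an ECG record given its header (``.hea``) file.

    Amplitudes are converted to mV using each channel's gain and
    baseline.  Format-212 signal files and the package's text dialect
    are supported.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FormatError(f"header file {header_path} not found")
    record_id, n_sig, fs, n_samples, specs = _parse_header(header_path)
    sig_path = header_path.parent / specs[0].file_name
    if not sig_path.exists():
        raise FormatError(f"signal file {sig_path} not found")

    if specs[0].fmt == "212":
        data = sig_path.read_bytes()
        if n_samples == 0:
            n_samples = (len(data) // 3 * 2) // n_sig
        flat = unpack_212(data, n_samples * n_sig)
        adu = flat.reshape(n_samples, n_sig).T
        signal = np.empty_like(adu, dtype=float)
        for c, sp in enumerate(specs):
            signal[c] = (adu[c] - sp.baseline) / sp.gain
    elif specs[0].fmt == "txt":
        rows = np.loadtxt(sig_path, delimiter=",", ndmin=2)
        if n_samples and rows.shape[0] != n_samples:
            raise IntegrityError(
                f"signal file holds {rows.shape[0]} samples, header "
                f"declares {n_samples}"
            )
        if rows.shape[1] != n_sig:
            raise IntegrityError(
                f"signal file has {rows.shape[1]} channels, header declares {n_sig}"
            )
        signal = rows.T / np.array([sp.gain for sp in specs])[:, None]
        signal -= np.array([sp.baseline / sp.gain for sp in specs])[:, None]
    else:
        raise FormatError(f"unsupported signal format {specs[0].fmt!r}")

    return EcgRecord(
        record_id=record_id,
        fs=fs,
        signal=signal,
        lead_names=[sp.description for sp in specs],
    )


# ---------------------------------------------------------------------------
# annotations

def _read_annotations_binary(data: bytes) -> list[BeatAnnotation]:
    out: list[BeatAnnotation] = []
    t = 0
    i = 0
    n = len(data) - len(data) % 2
    while i < n:
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        if word == 0:  # EOF
            break
        code, delta = word >> 10, word & 0x3FF
        if code == _SKIP:
            if i + 4 > n:
                break
            hi, lo = struct.unpack_from("<hH", data, i)
            i += 4
            t += (hi << 16) | lo
            continue
        if code in (_NUM, _SUB, _CHN):
            continue  # field modifiers; delta is the value, not time
        if code == _AUX:
            i += delta + (delta & 1)
            continue
        t += delta
        symbol = _CODE_TO_SYMBOL.get(code)
        if symbol is None or symbol in NON_BEAT_SYMBOLS:
            continue
        out.append(BeatAnnotation.from_symbol(t, symbol))
    return out


def _read_annotations_text(path: Path) -> list[BeatAnnotation]:
    out = []
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        idx, sym = ln.split(",")[:2]
        sym = sym.strip()
        if sym in NON_BEAT_SYMBOLS:
            continue
        out.append(BeatAnnotation.from_symbol(int(idx), sym))
    return out


def read_annotations(ann_path: str | Path) -> list[BeatAnnotation]:
    """Read beat annotations, sorted by sample index.

    Binary MIT annotation streams (``.atr``) and the text dialect
    (``sample_index,symbol`` per line) are both accepted; non-beat
    annotations (rhythm labels, artifacts) are dropped.
    """
    ann_path = Path(ann_path)
    if not ann_path.exists():
        raise FormatError(f"annotation file {ann_path} not found")
    if ann_path.suffix in (".txt", ".csv"):
        anns = _read_annotations_text(ann_path)
    else:
        anns = _read_annotations_binary(ann_path.read_bytes())
    return sorted(anns, key=lambda a: a.sample_index)


def _write_annotations_binary(annotations: Sequence[BeatAnnotation], path: Path) -> None:
    buf = bytearray()
    t = 0
    for ann in annotations:
        delta = ann.sample_index - t
        if delta < 0:
            raise ValueError("annotations must be sorted before writing")
        while delta > 1023:
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<hH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            t += delta
            delta = 0
        code = _SYMBOL_TO_CODE.get(ann.mit_symbol, _SYMBOL_TO_CODE["Q"])
        buf += struct.pack("<H", (code << 10) | delta)
        t = ann.sample_index
    buf += struct.pack("<H", 0)
    path.write_bytes(bytes(buf))


def write_record(
    record: EcgRecord,
    annotations: Iterable[BeatAnnotation],
    out_dir: str | Path,
    fmt: str = "212",
    gain: float = 200.0,
) -> dict[str, Path]:
    """Write a record (+ annotations) readable by :func:`read_record`
    and :func:`read_annotations`.

    With ``fmt="212"`` amplitudes are quantized to 12-bit ADC units at
    the given gain (default 200 ADU/mV, the MIT-BIH convention), so the
    read-back error is at most one quantization step (1/gain mV).  With
    ``fmt="txt"`` samples are stored as mV text at six decimals.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annotations = sorted(annotations, key=lambda a: a.sample_index)
    for ann in annotations:
        if not 0 <= ann.sample_index < record.n_samples:
            raise ValueError(
                f"annotation index {ann.sample_index} outside record of "
                f"{record.n_samples} samples"
            )

    rid = record.record_id
    header = out_dir / f"{rid}.hea"
    if fmt == "212":
        sig_name = f"{rid}.dat"
        adu = np.rint(record.signal * gain).astype(np.int64)
        adu = np.clip(adu, -2048, 2047)
        data = pack_212(adu.T.reshape(-1))
        (out_dir / sig_name).write_bytes(data)
        gain_tok = f"{gain:g}"
    elif fmt == "txt":
        sig_name = f"{rid}.txt"
        np.savetxt(out_dir / sig_name, record.signal.T, fmt="%.6f", delimiter=",")
        gain_tok = "1"
        fmt = "txt"
    else:
        raise ValueError(f"unsupported output format {fmt!r}")

    lines = [f"{rid} {record.n_channels} {record.fs:g} {record.n_samples}"]
    for name in record.lead_names:
        lines.append(f"{sig_name} {fmt} {gain_tok} 12 0 0 0 0 {name}")
    header.write_text("\n".join(lines) + "\n")

    paths = {"header": header, "signal": out_dir / sig_name}
    if fmt == "212":
        ann_path = out_dir / f"{rid}.atr"
        _write_annotations_binary(annotations, ann_path)
    else:
        ann_path = out_dir / f"{rid}.ann.csv"
        ann_path.write_text(
            "".join(f"{a.sample_index},{a.mit_symbol}\n" for a in annotations)
        )
    paths["annotations"] = ann_path
    return paths
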