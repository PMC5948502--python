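"""Text-format I/O for single-lead ECG records and beat annotations.

Two plain-text formats are canonical:

* **Record**: a header line ``fs=<float>,lead=<string>`` followed by one
  amplitude per line.  Amplitudes are written with up to 12 significant
  digits, which makes write→read→write byte-identical for canonical files.
* **Annotations**: tab-separated lines ``<sample_index>\\t<label>`` where the
  label is one of the five AAMI heartbeat classes N, S, V, F, Q
  (normal, supraventricular ectopic, ventricular ectopic, fusion, unknown).

Sample indices are 0-based throughout.  An optional adapter for WFDB-style
record/annotation pairs is provided via :func:`load_wfdb`; it requires the
``wfdb`` package and a caller-supplied mapping from native annotation symbols
to the 5-class alphabet (symbol mapping is deliberately the adapter caller's
responsibility).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: The five AAMI heartbeat classes, in canonical order.
AAMI_CLASSES: tuple[str, ...] = ("N", "S", "V", "F", "Q")
CLASS_TO_INDEX: dict[str, int] = {c: i for i, c in enumerate(AAMI_CLASSES)}

# 12 significant digits: enough that a canonical file round-trips exactly.
_FLOAT_FMT = "%.12g"


class FormatError(ValueError):
    """A record or annotation file violates the canonical text format."""


@dataclass
class Record:
    """A single-lead ECG record: sampled amplitudes plus metadata.

    Parameters
    ----------
    id : str
        Identifier (by convention the file stem).
    fs : float
        Sampling rate in Hz; must be positive.
    samples : array-like of float
        Amplitude series (mV or arbitrary units); non-empty, finite.
    lead : str
        Lead label, e.g. ``"II"``.
    """

    id: str
    fs: float
    samples: np.ndarray
    lead: str = "II"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not self.fs > 0:
            raise ValueError(f"record {self.id!r}: fs must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError(f"record {self.id!r}: samples must be a non-empty 1-D series")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"record {self.id!r}: samples contain NaN or Inf")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return len(self) / self.fs


@dataclass(frozen=True, order=True)
class Annotation:
    """A labelled R-peak position: 0-based sample index plus AAMI class."""

    sample_index: int
    label: str

    def __post_init__(self) -> None:
        if self.sample_index < 0:
            raise ValueError(f"annotation index must be >= 0, got {self.sample_index}")
        if self.label not in CLASS_TO_INDEX:
            raise ValueError(f"unknown class {self.label!r} (expected one of {AAMI_CLASSES})")


def read_record(path: str | Path) -> Record:
    """Parse a canonical record file.

    Raises :class:`FormatError` on a malformed header, a missing or
    non-positive sampling rate, or a non-numeric amplitude (the error message
    names the 1-based line number).
    """
    path = Path(path)
    with open(path, "r") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0]
    fields = dict(
        part.split("=", 1) for part in header.split(",") if "=" in part
    )
    if "fs" not in fields:
        raise FormatError(f"{path}: header must contain 'fs=<float>', got {header!r}")
    try:
        fs = float(fields["fs"])
    except ValueError:
        raise FormatError(f"{path}: non-numeric fs {fields['fs']!r}") from None
    if fs <= 0:
        raise FormatError(f"{path}: fs must be positive, got {fs}")
    lead = fields.get("lead", "II")
    samples = np.empty(len(lines) - 1, dtype=np.float64)
    for i, line in enumerate(lines[1:], start=2):
        try:
            samples[i - 2] = float(line)
        except ValueError:
            raise FormatError(f"{path}: non-numeric amplitude {line!r} at line {i}") from None
    return Record(id=path.stem, fs=fs, samples=samples, lead=lead)


def write_record(record: Record, path: str | Path) -> None:
    """Write a record in the canonical text format (12 significant digits)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"fs={_FLOAT_FMT % record.fs},lead={record.lead}\n")
        for v in record.samples:
            fh.write(_FLOAT_FMT % v)
            fh.write("\n")


def read_annotations(path: str | Path) -> list[Annotation]:
    """Parse an annotation TSV; returns annotations sorted by sample index.

    Duplicates are preserved; an out-of-alphabet label raises
    :class:`FormatError` naming the offending symbol.
    """
    path = Path(path)
    anns: list[Annotation] = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: expected '<index>\\t<label>' at line {lineno}")
            idx_str, label = parts
            try:
                idx = int(idx_str)
            except ValueError:
                raise FormatError(f"{path}: non-integer index {idx_str!r} at line {lineno}") from None
            if label not in CLASS_TO_INDEX:
                raise FormatError(f"{path}: unknown class {label!r} at line {lineno}")
            anns.append(Annotation(idx, label))
    anns.sort(key=lambda a: a.sample_index)  # stable: duplicates keep file order
    return anns


def write_annotations(annotations: list[Annotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(f"{a.sample_index}\t{a.label}\n")


def validate_annotations(record: Record, annotations: list[Annotation]) -> None:
    """Check every annotation index lies inside the record; raise otherwise.

    Called before any downstream stage consumes a record/annotation pair.
    """
    n = len(record)
    for a in annotations:
        if not (0 <= a.sample_index < n):
            raise ValueError(
                f"annotation index {a.sample_index} out of range for record "
                f"{record.id!r} of length {n}"
            )


def load_wfdb(record_path: str | Path, symbol_map: dict[str, str],
              annotator: str = "atr") -> tuple[Record, list[Annotation]]:
    """Optional adapter: read a WFDB record/annotation pair.

    Requires the ``wfdb`` package (``pip install litenet[wfdb]``).  The caller
    supplies ``symbol_map``, mapping native annotation symbols to the five
    AAMI classes; symbols absent from the map are dropped.
    """
    try:
        import wfdb  # type: ignore
    except ImportError as exc:  # pragma: no cover - exercised only without wfdb
        raise ImportError(
            "the WFDB adapter requires the optional 'wfdb' package; "
            "install with: pip install litenet[wfdb]"
        ) from exc
    record_path = str(record_path)
    rec = wfdb.rdrecord(record_path, channels=[0])
    ann = wfdb.rdann(record_path, annotator)
    record = Record(
        id=Path(record_path).name,
        fs=float(rec.fs),
        samples=np.asarray(rec.p_signal[:, 0], dtype=np.float64),
        lead=str(rec.sig_name[0]) if rec.sig_name else "II",
    )
    annotations = [
        Annotation(int(s), symbol_map[sym])
        for s, sym in zip(ann.sample, ann.symbol)
        if sym in symbol_map
    ]
    annotations.sort(key=lambda a: a.sample_index)
    validate_annotations(record, annotations)
    return record, annotations
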