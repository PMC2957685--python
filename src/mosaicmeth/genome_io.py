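"""Genome and interval-table input/output.

Reads genomic FASTA into :class:`SequenceRecord` objects, enumerates fixed
and sliding coordinate windows over them, and parses BED-like interval
tables (CpG-island annotation, per-window methylation-level tables).

All coordinates are 0-based, half-open, matching BED conventions. UCSC
``cpgIslandExt`` rows therefore import without any shift.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "IntervalRecord",
    "read_fasta",
    "iter_fixed_windows",
    "iter_sliding_windows",
    "read_interval_table",
    "write_interval_table",
]

# byte codes used throughout: A=0, C=1, G=2, T=3, ambiguous=4
_CODE_A, _CODE_C, _CODE_G, _CODE_T, _CODE_AMBIG = 0, 1, 2, 3, 4

_CODE_LUT = np.full(256, _CODE_AMBIG, dtype=np.uint8)
for _ch, _code in (("A", _CODE_A), ("C", _CODE_C), ("G", _CODE_G), ("T", _CODE_T)):
    _CODE_LUT[ord(_ch)] = _code
    _CODE_LUT[ord(_ch.lower())] = _code


@dataclass
class SequenceRecord:
    """One chromosome/scaffold.

    Soft-masked (lowercase) bases keep their base identity; any residue
    outside A/C/G/T (either case) is treated as ambiguous.
    """

    name: str
    sequence: str
    _codes: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def codes(self) -> np.ndarray:
        """uint8 base codes (A=0, C=1, G=2, T=3, ambiguous=4), cached."""
        if self._codes is None:
            raw = np.frombuffer(self.sequence.encode("ascii", "replace"), dtype=np.uint8)
            self._codes = _CODE_LUT[raw]
        return self._codes


def _open_text(path: Union[str, Path]):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "rt", encoding="ascii")


def read_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    """Read a (optionally gzipped, multi-record) FASTA file.

    Raises ``ValueError`` on an empty file, on leading non-header content
    (naming the offending line), or on duplicate record names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: expected FASTA header '>' "
                    f"but found {line.strip()[:30]!r}"
                )
            break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    records = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate record name {rec.id!r}")
            seen.add(rec.id)
            records.append(SequenceRecord(name=rec.id, sequence=str(rec.seq)))
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    return records


def iter_fixed_windows(length_or_record, width: int) -> Iterator[tuple[int, int]]:
    """Abutting, non-overlapping windows starting at 0.

    A trailing fragment shorter than ``width`` is not emitted; a sequence
    shorter than ``width`` yields nothing.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    length = length_or_record if isinstance(length_or_record, int) else len(length_or_record)
    for start in range(0, length - width + 1, width):
        yield (start, start + width)


def iter_sliding_windows(length_or_record, width: int, step: int) -> Iterator[tuple[int, int]]:
    """Complete windows at starts 0, step, 2*step, ..."""
    if width <= 0:
        raise ValueError("window width must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    length = length_or_record if isinstance(length_or_record, int) else len(length_or_record)
    for start in range(0, length - width + 1, step):
        yield (start, start + width)


@dataclass(frozen=True)
class IntervalRecord:
    """A BED-like interval, optionally carrying a methylation level in [0, 1]."""

    chrom: str
    start: int
    end: int
    payload: Optional[float] = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def read_interval_table(
    path: Union[str, Path],
    with_payload: bool = False,
    payload_scale: str = "fraction",
) -> list[IntervalRecord]:
    """Parse a tab-separated BED3/BED4 table.

    Columns are chrom, start, end and optionally a payload. With
    ``with_payload=True`` the fourth column is parsed as a methylation
    level; ``payload_scale`` declares the dialect: ``"fraction"`` for
    values already in [0, 1] (binary 1/0 status columns parse as
    levels 1.0/0.0) or ``"percent"`` for values in [0, 100], which are
    divided by 100. Rows failing validation raise with their line number.
    """
    if payload_scale not in ("fraction", "percent"):
        raise ValueError(f"unknown payload_scale {payload_scale!r}")
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            payload = None
            if with_payload:
                if len(fields) < 4:
                    raise ValueError(f"{path}: line {lineno}: payload column missing")
                try:
                    payload = float(fields[3])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: line {lineno}: non-numeric payload {fields[3]!r}"
                    ) from exc
                if payload_scale == "percent":
                    payload /= 100.0
                if not 0.0 <= payload <= 1.0:
                    raise ValueError(
                        f"{path}: line {lineno}: methylation level {payload} outside [0, 1]"
                    )
            try:
                records.append(IntervalRecord(chrom, start, end, payload))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_interval_table(path: Union[str, Path], records, with_payload: bool = False) -> None:
    """Write intervals as tab-separated BED3/BED4."""
    with open(path, "wt", encoding="ascii") as fh:
        for rec in records:
            if with_payload:
                fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.payload:g}\n")
            else:
                fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\n")
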