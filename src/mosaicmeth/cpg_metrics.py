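"""Per-window CpG statistics and the genome-wide score histogram.

The CpG score of a window is the ratio of observed to expected CpG
dinucleotide counts, ``n_CpG * L / (n_C * n_G)`` with L the full window
width (the UCSC observed/expected convention). Windows with more than 50
ambiguous residues, or with no C or no G at all, are marked invalid and
excluded from every downstream computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genome_io import IntervalRecord, SequenceRecord

__all__ = [
    "WindowRecord",
    "ScoreHistogram",
    "count_window",
    "cpg_score",
    "window_scores",
    "build_histogram",
    "cpg_island_fraction",
    "windows_to_frame",
]

AMBIGUITY_MAX = 50  # ambiguous residues tolerated per 2-kb window
DEFAULT_BIN_WIDTH = 0.02
HISTOGRAM_TOP = 2.0  # scores >= this accumulate in the final bin


@dataclass
class WindowRecord:
    """Counts and CpG score for one genomic window (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    n_C: int
    n_G: int
    n_CpG: int
    n_ambiguous: int
    score: float  # NaN when undefined (n_C * n_G == 0)
    valid: bool

    @property
    def width(self) -> int:
        return self.end - self.start


def count_window(seq: SequenceRecord, start: int, end: int) -> tuple[int, int, int, int]:
    """Count C, G, CpG dinucleotides and ambiguous residues in [start, end).

    CpG occurrences are counted strictly inside the window (first base at
    positions start .. end-2); counting is case-insensitive and any
    non-ACGT residue both increments the ambiguity count and blocks
    participation in a CpG.
    """
    if not (0 <= start < end <= len(seq)):
        raise ValueError(f"window [{start}, {end}) outside sequence of length {len(seq)}")
    codes = seq.codes()[start:end]
    n_c = int(np.count_nonzero(codes == 1))
    n_g = int(np.count_nonzero(codes == 2))
    n_ambig = int(np.count_nonzero(codes == 4))
    n_cpg = int(np.count_nonzero((codes[:-1] == 1) & (codes[1:] == 2)))
    return n_c, n_g, n_cpg, n_ambig


def cpg_score(n_C: int, n_G: int, n_CpG: int, window_length: int) -> float:
    """Observed/expected CpG ratio, ``n_CpG * L / (n_C * n_G)``.

    Returns NaN (undefined) when the expected count is zero.
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    if n_C * n_G == 0:
        return math.nan
    return n_CpG * window_length / (n_C * n_G)


def _chromosome_window_counts(
    codes: np.ndarray, starts: np.ndarray, width: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-window counts via cumulative sums."""
    cum_c = np.concatenate(([0], np.cumsum(codes == 1)))
    cum_g = np.concatenate(([0], np.cumsum(codes == 2)))
    cum_n = np.concatenate(([0], np.cumsum(codes == 4)))
    is_cpg = (codes[:-1] == 1) & (codes[1:] == 2)
    cum_cpg = np.concatenate(([0], np.cumsum(is_cpg)))
    ends = starts + width
    n_c = cum_c[ends] - cum_c[starts]
    n_g = cum_g[ends] - cum_g[starts]
    n_ambig = cum_n[ends] - cum_n[starts]
    # CpG with first base in [start, end-1)
    n_cpg = cum_cpg[ends - 1] - cum_cpg[starts]
    return n_c, n_g, n_cpg, n_ambig


def window_scores(
    genome: Union[SequenceRecord, Iterable[SequenceRecord]],
    mode: str = "fixed",
    width: int = 2000,
    step: int = 100,
    ambiguity_max: int = AMBIGUITY_MAX,
) -> list[WindowRecord]:
    """Score every complete window of each sequence record.

    ``mode="fixed"`` uses abutting windows (the histogram/fit input);
    ``mode="sliding"`` moves the window by ``step`` (the classification
    input). Windows restart at 0 on each record. A window is invalid when
    it holds more than ``ambiguity_max`` ambiguous residues (exactly that
    many is kept) or when its score is undefined.
    """
    if isinstance(genome, SequenceRecord):
        genome = [genome]
    genome = list(genome)
    if not genome:
        raise ValueError("empty genome")
    if mode == "fixed":
        eff_step = width
    elif mode == "sliding":
        eff_step = step
    else:
        raise ValueError(f"unknown mode {mode!r}")

    records: list[WindowRecord] = []
    for seq in genome:
        if len(seq) < width:
            continue
        starts = np.arange(0, len(seq) - width + 1, eff_step)
        n_c, n_g, n_cpg, n_ambig = _chromosome_window_counts(seq.codes(), starts, width)
        expected = n_c.astype(np.float64) * n_g
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = np.where(expected > 0, n_cpg * float(width) / expected, np.nan)
        valid = (n_ambig <= ambiguity_max) & (expected > 0)
        records.extend(
            WindowRecord(
                seq.name,
                int(s),
                int(s) + width,
                int(c),
                int(g),
                int(cg),
                int(na),
                float(sc),
                bool(v),
            )
            for s, c, g, cg, na, sc, v in zip(starts, n_c, n_g, n_cpg, n_ambig, scores, valid)
        )
    return records


@dataclass
class ScoreHistogram:
    """Binned genome-wide CpG-score counts.

    Half-open bins of ``bin_width`` starting at 0; scores at or above the
    top edge accumulate in the final (overflow) bin.
    """

    bin_width: float
    counts: np.ndarray  # integer counts per bin
    n_windows: int
    lower_edge: float = 0.0
    top: float = HISTOGRAM_TOP

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def edges(self) -> np.ndarray:
        return self.lower_edge + self.bin_width * np.arange(self.n_bins + 1)

    @property
    def midpoints(self) -> np.ndarray:
        return self.lower_edge + self.bin_width * (np.arange(self.n_bins) + 0.5)

    @classmethod
    def from_scores(
        cls, scores: Sequence[float], bin_width: float = DEFAULT_BIN_WIDTH, top: float = HISTOGRAM_TOP
    ) -> "ScoreHistogram":
        scores = np.asarray(scores, dtype=np.float64)
        if scores.size == 0:
            raise ValueError("no scorable windows")
        if np.any(scores < 0) or np.any(~np.isfinite(scores)):
            raise ValueError("scores must be finite and non-negative")
        n_bins = int(round(top / bin_width))
        idx = np.minimum(np.floor(scores / bin_width).astype(np.int64), n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        return cls(bin_width=bin_width, counts=counts, n_windows=int(scores.size), top=top)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lower": self.edges[:-1],
                "bin_upper": self.edges[1:],
                "count": self.counts,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def build_histogram(
    records: Iterable[WindowRecord], bin_width: float = DEFAULT_BIN_WIDTH
) -> ScoreHistogram:
    """Bin the scores of valid windows; invalid windows are excluded."""
    scores = [r.score for r in records if r.valid]
    if not scores:
        raise ValueError("no scorable windows")
    return ScoreHistogram.from_scores(scores, bin_width=bin_width)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def cpg_island_fraction(islands: Iterable[IntervalRecord], genome_length: int) -> float:
    """Fraction of the genome covered by (merged) CpG-island annotation."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for isl in islands:
        if isl.end > genome_length:
            raise ValueError(
                f"island {isl.chrom}:{isl.start}-{isl.end} extends past genome length {genome_length}"
            )
        by_chrom.setdefault(isl.chrom, []).append((isl.start, isl.end))
    covered = sum(
        end - start for ivs in by_chrom.values() for start, end in _merge_intervals(ivs)
    )
    return covered / genome_length


def windows_to_frame(records: Iterable[WindowRecord]) -> pd.DataFrame:
    """Window records as a TSV-ready DataFrame."""
    records = list(records)
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "start": [r.start for r in records],
            "end": [r.end for r in records],
            "n_C": [r.n_C for r in records],
            "n_G": [r.n_G for r in records],
            "n_CpG": [r.n_CpG for r in records],
            "n_ambiguous": [r.n_ambiguous for r in records],
            "score": [r.score for r in records],
            "valid": [r.valid for r in records],
        }
    )
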