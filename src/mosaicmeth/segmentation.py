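"""Classify sliding windows, build and smooth the 100-bp binary track,
extract methylated/unmethylated segments and compute the genome indices.

The per-species boundary from the mixture decomposition labels every
2-kb sliding window (step 100 bp) methylated (score below the boundary)
or unmethylated. Each window's label is written to the 100-bp bin
containing the window's midpoint, yielding a binary track over the
chromosome. The track is smoothed by a centered 2-kb majority vote,
maximal constant runs become segments, and the per-status length
statistics give the two indices: mean unmethylated length over mean
methylated length, and the same ratio for the standard deviations.
Values near 1 indicate a mosaic pattern (alternating tracts of similar
extent); values far below 1 indicate the global vertebrate pattern of
long methylated tracts punctuated by short unmethylated islands.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cpg_metrics import WindowRecord

__all__ = [
    "LABEL_NO_DATA",
    "LABEL_METH",
    "LABEL_UNMETH",
    "BinaryTrack",
    "MethylationSegment",
    "GenomeIndices",
    "classify_windows",
    "project_to_bins",
    "smooth_track",
    "extract_segments",
    "segment_statistics",
    "length_ratio_indices",
    "write_segments_bed",
]

LABEL_NO_DATA = 0
LABEL_METH = 1
LABEL_UNMETH = 2

DEFAULT_BIN_SIZE = 100
DEFAULT_SMOOTH_WINDOW = 2000

_STATUS_NAMES = {LABEL_METH: "M", LABEL_UNMETH: "U"}


@dataclass
class BinaryTrack:
    """Per-100-bp methylation-status labels for one chromosome.

    Bin i covers [i*bin_size, (i+1)*bin_size). ``labels`` holds
    LABEL_NO_DATA / LABEL_METH / LABEL_UNMETH codes.
    """

    chrom: str
    bin_size: int
    labels: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class MethylationSegment:
    """A maximal run of one methylation status (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    status: str  # "M" or "U"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeIndices:
    """Per-genome summary: boundary, per-status length statistics, ratios."""

    boundary: float
    meth_mean: float
    meth_sd: float
    unmeth_mean: float
    unmeth_sd: float
    ratio_lengths: float
    ratio_sds: float
    n_meth_segments: int
    n_unmeth_segments: int

    def to_dict(self) -> dict:
        return {
            "boundary": self.boundary,
            "meth_mean": self.meth_mean,
            "meth_sd": self.meth_sd,
            "unmeth_mean": self.unmeth_mean,
            "unmeth_sd": self.unmeth_sd,
            "ratio_lengths": self.ratio_lengths,
            "ratio_sds": self.ratio_sds,
            "n_meth_segments": self.n_meth_segments,
            "n_unmeth_segments": self.n_unmeth_segments,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "wt") as fh:
                fh.write(text + "\n")
        return text

    def to_frame(self) -> pd.DataFrame:
        """One row in the column order boundary, meth mean/SD, unmeth
        mean/SD, ratio of lengths, ratio of SDs."""
        return pd.DataFrame(
            [
                {
                    "boundary": self.boundary,
                    "meth_mean": self.meth_mean,
                    "meth_sd": self.meth_sd,
                    "unmeth_mean": self.unmeth_mean,
                    "unmeth_sd": self.unmeth_sd,
                    "ratio_lengths": self.ratio_lengths,
                    "ratio_sds": self.ratio_sds,
                }
            ]
        )


def classify_windows(
    records: Sequence[WindowRecord], boundary: float, tie: str = "unmeth"
) -> np.ndarray:
    """Label each window methylated/unmethylated against the boundary.

    score < boundary -> methylated; score > boundary -> unmethylated;
    score == boundary -> per the ``tie`` rule ("unmeth" default);
    invalid windows -> no_data.
    """
    if boundary <= 0:
        raise ValueError("boundary must be positive")
    if tie not in ("unmeth", "meth"):
        raise ValueError(f"unknown tie rule {tie!r}")
    labels = np.empty(len(records), dtype=np.int8)
    for i, rec in enumerate(records):
        if not rec.valid:
            labels[i] = LABEL_NO_DATA
        elif rec.score < boundary:
            labels[i] = LABEL_METH
        elif rec.score > boundary:
            labels[i] = LABEL_UNMETH
        else:
            labels[i] = LABEL_METH if tie == "meth" else LABEL_UNMETH
    return labels


def project_to_bins(
    records: Sequence[WindowRecord],
    labels: np.ndarray,
    chrom_length: int,
    bin_size: int = DEFAULT_BIN_SIZE,
    placement: str = "midpoint",
) -> BinaryTrack:
    """Project window labels onto a 100-bp binary track for one chromosome.

    Each window's label is written to the single bin containing the
    window's midpoint (``placement="midpoint"``, default) or its start
    (``placement="start"``). Bins receiving no label are no_data.
    """
    if len(records) != len(labels):
        raise ValueError("records and labels length mismatch")
    if placement not in ("midpoint", "start"):
        raise ValueError(f"unknown placement {placement!r}")
    chroms = {r.chrom for r in records}
    if len(chroms) > 1:
        raise ValueError(f"records span multiple chromosomes: {sorted(chroms)}")
    n_bins = chrom_length // bin_size
    track = np.full(n_bins, LABEL_NO_DATA, dtype=np.int8)
    for rec, lab in zip(records, labels):
        pos = (rec.start + rec.end) // 2 if placement == "midpoint" else rec.start
        b = pos // bin_size
        if 0 <= b < n_bins:
            track[b] = lab
    chrom = records[0].chrom if records else ""
    return BinaryTrack(chrom=chrom, bin_size=bin_size, labels=track)


def smooth_track(track: BinaryTrack, window: int = DEFAULT_SMOOTH_WINDOW) -> BinaryTrack:
    """Majority-vote smoothing with a centered window.

    Each bin's smoothed label is the majority among labeled bins inside
    the ``window``-bp window centered on the bin (bins i-k .. i+k-1 for a
    window of 2k bins). Exact ties carry the previous (left neighbour's)
    smoothed label, or the bin's own label at a chromosome start.
    no_data bins stay no_data and never vote.
    """
    if window % track.bin_size != 0:
        raise ValueError("smoothing window must be a multiple of bin_size")
    half = window // track.bin_size // 2
    labels = track.labels
    n = len(labels)
    is_m = (labels == LABEL_METH).astype(np.int64)
    is_u = (labels == LABEL_UNMETH).astype(np.int64)
    cum_m = np.concatenate(([0], np.cumsum(is_m)))
    cum_u = np.concatenate(([0], np.cumsum(is_u)))
    out = np.full(n, LABEL_NO_DATA, dtype=np.int8)
    prev = LABEL_NO_DATA
    for i in range(n):
        if labels[i] == LABEL_NO_DATA:
            prev = LABEL_NO_DATA
            continue
        lo = max(0, i - half)
        hi = min(n, i + half)
        m = cum_m[hi] - cum_m[lo]
        u = cum_u[hi] - cum_u[lo]
        if m > u:
            out[i] = LABEL_METH
        elif u > m:
            out[i] = LABEL_UNMETH
        else:
            out[i] = prev if prev != LABEL_NO_DATA else labels[i]
        prev = out[i]
    return BinaryTrack(chrom=track.chrom, bin_size=track.bin_size, labels=out)


def extract_segments(track: BinaryTrack) -> list[MethylationSegment]:
    """Run-length encode the track into segments; no_data splits runs."""
    labels = track.labels
    segments: list[MethylationSegment] = []
    n = len(labels)
    i = 0
    while i < n:
        lab = labels[i]
        j = i
        while j < n and labels[j] == lab:
            j += 1
        if lab != LABEL_NO_DATA:
            segments.append(
                MethylationSegment(
                    chrom=track.chrom,
                    start=i * track.bin_size,
                    end=j * track.bin_size,
                    status=_STATUS_NAMES[int(lab)],
                )
            )
        i = j
    return segments


def length_ratio_indices(
    meth_mean: float, meth_sd: float, unmeth_mean: float, unmeth_sd: float
) -> tuple[float, float]:
    """The two pattern indices from per-status length statistics.

    ratio_lengths = unmeth_mean / meth_mean;
    ratio_sds = unmeth_sd / meth_sd. NaN when a denominator is zero.
    """
    ratio_lengths = unmeth_mean / meth_mean if meth_mean > 0 else math.nan
    if meth_sd > 0:
        ratio_sds = unmeth_sd / meth_sd
    elif unmeth_sd == meth_sd == 0:
        ratio_sds = 1.0  # both classes perfectly uniform: equal scatter
    else:
        ratio_sds = math.nan
    return ratio_lengths, ratio_sds


def segment_statistics(
    segments: Iterable[MethylationSegment], boundary: float, ddof: int = 0
) -> GenomeIndices:
    """Per-status mean/SD of segment lengths and the two ratio indices.

    SDs use the population formula by default (``ddof=0``). If one
    status class is empty the ratios are NaN and a warning is issued.
    """
    meth = np.array([s.length for s in segments if s.status == "M"], dtype=np.float64)
    unmeth = np.array([s.length for s in segments if s.status == "U"], dtype=np.float64)

    def _stats(lengths: np.ndarray) -> tuple[float, float]:
        if lengths.size == 0:
            return math.nan, math.nan
        return float(lengths.mean()), float(lengths.std(ddof=ddof))

    meth_mean, meth_sd = _stats(meth)
    unmeth_mean, unmeth_sd = _stats(unmeth)
    if meth.size == 0 or unmeth.size == 0:
        warnings.warn(
            "one methylation-status class has no segments; ratio indices undefined",
            RuntimeWarning,
        )
        ratio_lengths = ratio_sds = math.nan
    else:
        ratio_lengths, ratio_sds = length_ratio_indices(
            meth_mean, meth_sd, unmeth_mean, unmeth_sd
        )
    return GenomeIndices(
        boundary=boundary,
        meth_mean=meth_mean,
        meth_sd=meth_sd,
        unmeth_mean=unmeth_mean,
        unmeth_sd=unmeth_sd,
        ratio_lengths=ratio_lengths,
        ratio_sds=ratio_sds,
        n_meth_segments=int(meth.size),
        n_unmeth_segments=int(unmeth.size),
    )


def write_segments_bed(path, segments: Iterable[MethylationSegment]) -> None:
    """Write segments as BED4 (chrom, start, end, M|U)."""
    with open(path, "wt", encoding="ascii") as fh:
        for seg in segments:
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.status}\n")
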