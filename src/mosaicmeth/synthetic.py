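"""Synthetic mosaic genomes with known methylation-tract ground truth.

Emulates a genome built of alternating methylated-like (CpG-depleted)
and unmethylated-like (CpG-rich) tracts. Within a tract, sequence is
drawn from a first-order Markov chain over A/C/G/T whose stationary base
composition matches the requested G+C content and whose C->G transition
probability is solved (by iterative proportional fitting of the
dinucleotide joint distribution, with the CG cell pinned) so that the
tract's expected CpG observed/expected ratio hits the per-state target.
Tract lengths are drawn from a gamma family whose SD is of the same
order as its mean, so segment-length scatter resembles real genomes.

Also provides a direct sampler of two-Gaussian score mixtures used to
exercise the decomposition step in isolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .cpg_metrics import ScoreHistogram
from .genome_io import SequenceRecord
from .segmentation import MethylationSegment

__all__ = [
    "MosaicSpec",
    "MosaicGenome",
    "solve_transition_matrix",
    "generate_mosaic_genome",
    "generate_mixture_scores",
]

_BASES = "ACGT"
_IDX_C, _IDX_G = 1, 2

# true methylation levels written for the validation stratification
METH_LEVEL = 0.9
UNMETH_LEVEL = 0.1


@dataclass
class MosaicSpec:
    """Ground-truth parameters of a simulated mosaic genome.

    Tract-length means default to the scale seen in mosaic genomes
    (roughly 5-6.5 kb); per-state CpG o/e targets default to a strongly
    methylated-like 0.25 and an unmethylated-like 1.0; G+C content
    defaults to 0.42. ``gap_rate`` is the expected fraction of the
    genome overwritten by N runs (mean run length 500 bp).
    """

    total_length: int = 10_000_000
    meth_tract_mean: float = 5000.0
    unmeth_tract_mean: float = 6500.0
    tract_shape: float = 1.2  # gamma shape; SD = mean/sqrt(shape)
    meth_oe: float = 0.25
    unmeth_oe: float = 1.0
    gc_content: float = 0.42
    gap_rate: float = 0.0
    seed: int = 0
    chrom_name: str = "chrS"

    def validate(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if not self.meth_oe < self.unmeth_oe:
            raise ValueError("meth_oe must be below unmeth_oe")
        if min(self.meth_tract_mean, self.unmeth_tract_mean) < 2000:
            raise ValueError("tract means must be >= 2000 bp")
        if self.total_length <= 0 or self.tract_shape <= 0:
            raise ValueError("total_length and tract_shape must be positive")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValueError("gap_rate must be in [0, 1)")
        pc = pg = self.gc_content / 2.0
        for oe in (self.meth_oe, self.unmeth_oe):
            if oe < 0 or oe * pc * pg >= min(pc, pg):
                raise ValueError(
                    f"CpG o/e target {oe} infeasible at G+C {self.gc_content}"
                )


@dataclass
class MosaicGenome:
    """A generated genome, its truth segments, and a realized-o/e report."""

    record: SequenceRecord
    truth_segments: list[MethylationSegment]
    report: dict
    spec: MosaicSpec

    def truth_levels(self, window: int = 2000) -> list[tuple[str, int, int, float]]:
        """Per-2-kb-window true methylation level rows (chrom, start, end, level).

        The level is the tract-level value (0.9 methylated / 0.1
        unmethylated) averaged over the bases of the window, so windows
        straddling a tract boundary get intermediate values.
        """
        length = len(self.record)
        level = np.empty(length, dtype=np.float32)
        for seg in self.truth_segments:
            level[seg.start : seg.end] = METH_LEVEL if seg.status == "M" else UNMETH_LEVEL
        rows = []
        for start in range(0, length - window + 1, window):
            rows.append(
                (
                    self.record.name,
                    start,
                    start + window,
                    float(level[start : start + window].mean()),
                )
            )
        return rows

    def write(self, out_dir) -> None:
        """Write genome.fa, truth.bed, truth_levels.tsv and spec.json."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.fa", "wt") as fh:
            fh.write(f">{self.record.name}\n")
            seq = self.record.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
        with open(out / "truth.bed", "wt") as fh:
            for seg in self.truth_segments:
                fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.status}\n")
        with open(out / "truth_levels.tsv", "wt") as fh:
            for chrom, start, end, lev in self.truth_levels():
                fh.write(f"{chrom}\t{start}\t{end}\t{lev:.4f}\n")
        with open(out / "spec.json", "wt") as fh:
            json.dump(asdict(self.spec), fh, indent=2)
            fh.write("\n")


def solve_transition_matrix(gc_content: float, target_oe: float, n_iter: int = 500) -> np.ndarray:
    """First-order Markov transition matrix with stationary composition
    (A,C,G,T) = ((1-gc)/2, gc/2, gc/2, (1-gc)/2) and CG dinucleotide
    frequency ``target_oe * pC * pG``.

    The dinucleotide joint distribution is found by iterative
    proportional fitting with the CG cell pinned; because its row and
    column marginals both equal the base composition, that composition
    is stationary for the derived chain and the expected window-level
    CpG o/e equals the target (up to the (L-1)/L edge factor).
    """
    pa = pt = (1.0 - gc_content) / 2.0
    pc = pg = gc_content / 2.0
    pi = np.array([pa, pc, pg, pt])
    target_cg = target_oe * pc * pg
    joint = np.outer(pi, pi)
    for _ in range(n_iter):
        joint[_IDX_C, _IDX_G] = target_cg
        joint *= (pi / joint.sum(axis=1))[:, None]
        joint[_IDX_C, _IDX_G] = target_cg
        joint *= (pi / joint.sum(axis=0))[None, :]
    joint[_IDX_C, _IDX_G] = target_cg
    joint /= joint.sum()
    trans = joint / joint.sum(axis=1, keepdims=True)
    return trans


def _sample_markov(trans: np.ndarray, n: int, first: int, rng: np.random.Generator) -> list[int]:
    """Sample a Markov path of length n starting from state ``first``."""
    cum = np.cumsum(trans, axis=1)
    cum_rows = [tuple(row[:3]) for row in cum]
    u = rng.random(n).tolist()
    out = [0] * n
    s = first
    for i, ui in enumerate(u):
        c0, c1, c2 = cum_rows[s]
        if ui < c0:
            s = 0
        elif ui < c1:
            s = 1
        elif ui < c2:
            s = 2
        else:
            s = 3
        out[i] = s
    return out


def generate_mosaic_genome(spec: MosaicSpec) -> MosaicGenome:
    """Generate an alternating-state mosaic genome, fully seed-reproducible."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pi = np.array(
        [
            (1 - spec.gc_content) / 2,
            spec.gc_content / 2,
            spec.gc_content / 2,
            (1 - spec.gc_content) / 2,
        ]
    )
    trans = {
        "M": solve_transition_matrix(spec.gc_content, spec.meth_oe),
        "U": solve_transition_matrix(spec.gc_content, spec.unmeth_oe),
    }
    means = {"M": spec.meth_tract_mean, "U": spec.unmeth_tract_mean}

    # alternate states, first state chosen at random
    state = "M" if rng.random() < 0.5 else "U"
    segments: list[MethylationSegment] = []
    codes: list[int] = []
    pos = 0
    first = int(rng.choice(4, p=pi))
    while pos < spec.total_length:
        tract_len = int(
            round(rng.gamma(spec.tract_shape, means[state] / spec.tract_shape))
        )
        tract_len = max(tract_len, 100)
        tract_len = min(tract_len, spec.total_length - pos)
        path = _sample_markov(trans[state], tract_len, first, rng)
        codes.extend(path)
        first = path[-1]
        segments.append(
            MethylationSegment(spec.chrom_name, pos, pos + tract_len, state)
        )
        pos += tract_len
        state = "U" if state == "M" else "M"

    arr = np.array(codes, dtype=np.uint8)
    if spec.gap_rate > 0:
        target_gap = spec.gap_rate * spec.total_length
        placed = 0
        while placed < target_gap:
            glen = max(1, int(round(rng.gamma(1.0, 500.0))))
            gstart = int(rng.integers(0, max(1, spec.total_length - glen)))
            arr[gstart : gstart + glen] = 255  # N marker
            placed += glen

    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq_bytes = np.where(arr == 255, np.uint8(ord("N")), lut[np.minimum(arr, 3)])
    sequence = seq_bytes.tobytes().decode("ascii")
    record = SequenceRecord(name=spec.chrom_name, sequence=sequence)

    report = _realized_oe_report(record, segments)
    return MosaicGenome(record=record, truth_segments=segments, report=report, spec=spec)


def _realized_oe_report(record: SequenceRecord, segments, window: int = 2000) -> dict:
    """Mean window CpG o/e per truth state, over windows fully inside a tract."""
    from .cpg_metrics import window_scores

    recs = window_scores(record, mode="fixed", width=window)
    state_at = np.empty(len(record), dtype="U1")
    for seg in segments:
        state_at[seg.start : seg.end] = seg.status
    sums = {"M": [], "U": []}
    for rec in recs:
        if not rec.valid:
            continue
        states = state_at[rec.start : rec.end]
        if (states == states[0]).all() and states[0] in sums:
            sums[str(states[0])].append(rec.score)
    return {
        "meth_oe_realized": float(np.mean(sums["M"])) if sums["M"] else math.nan,
        "unmeth_oe_realized": float(np.mean(sums["U"])) if sums["U"] else math.nan,
        "n_meth_windows": len(sums["M"]),
        "n_unmeth_windows": len(sums["U"]),
    }


def generate_mixture_scores(
    w1: float,
    mu1: float,
    sd1: float,
    mu2: float,
    sd2: float,
    n: int,
    seed: int,
    bin_width: float = 0.02,
) -> tuple[np.ndarray, ScoreHistogram]:
    """Draw n scores from w1*N(mu1,sd1) + (1-w1)*N(mu2,sd2), truncated at 0.

    Negative draws are rejected and redrawn, so the realized component
    shapes are the positive-truncated Gaussians. Returns the sample and
    its histogram at the standard bin width.
    """
    if not 0.0 <= w1 <= 1.0:
        raise ValueError("w1 must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    comp = rng.random(n) >= w1  # False -> component 1
    mus = np.where(comp, mu2, mu1)
    sds = np.where(comp, sd2, sd1)
    x = rng.normal(mus, sds)
    bad = x < 0
    while bad.any():
        x[bad] = rng.normal(mus[bad], sds[bad])
        bad = x < 0
    hist = ScoreHistogram.from_scores(x, bin_width=bin_width)
    return x, hist
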