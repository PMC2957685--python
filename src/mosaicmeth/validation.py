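"""Stratify scored windows by independently measured methylation levels.

When per-window mean methylation levels are available (bisulfite
summaries, or binary 1/0 statuses treated as levels 1.0/0.0), windows
with levels in [0.7, 1.0] are called hypermethylated and those in
[0, 0.3] hypomethylated. If the CpG score indeed separates the two
states, the two strata should form well-separated, bell-shaped score
histograms — the empirical justification for decomposing the pooled
distribution into two Gaussians.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cpg_metrics import DEFAULT_BIN_WIDTH, ScoreHistogram, WindowRecord
from .genome_io import IntervalRecord

__all__ = ["StratifiedHistograms", "stratify_by_methylation"]

HYPER_RANGE = (0.7, 1.0)
HYPO_RANGE = (0.0, 0.3)


@dataclass
class StratifiedHistograms:
    """Score histograms of all / hypermethylated / hypomethylated windows."""

    all: ScoreHistogram
    hyper: ScoreHistogram
    hypo: ScoreHistogram
    n_unassigned: int  # windows with levels between the two ranges

    def write_tsvs(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.all.write_tsv(out / "histogram_all.tsv")
        self.hyper.write_tsv(out / "histogram_hyper.tsv")
        self.hypo.write_tsv(out / "histogram_hypo.tsv")


def stratify_by_methylation(
    records: Sequence[WindowRecord],
    levels: Iterable[IntervalRecord],
    hyper_range: tuple[float, float] = HYPER_RANGE,
    hypo_range: tuple[float, float] = HYPO_RANGE,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> StratifiedHistograms:
    """Join windows to measured levels and build per-stratum histograms.

    Levels join to windows by exact (chrom, start, end); both range
    endpoints are closed, so a level of exactly 0.7 is hypermethylated
    and exactly 0.3 hypomethylated. Duplicate level rows for one window,
    or a join with no matches at all, raise errors. Only valid windows
    enter the histograms.
    """
    level_map: dict[tuple[str, int, int], float] = {}
    for iv in levels:
        key = (iv.chrom, iv.start, iv.end)
        if key in level_map:
            raise ValueError(f"duplicate methylation-level row for window {key}")
        if iv.payload is None:
            raise ValueError(f"methylation-level row {key} has no level value")
        level_map[key] = iv.payload

    all_scores, hyper_scores, hypo_scores = [], [], []
    n_unassigned = 0
    n_joined = 0
    for rec in records:
        if not rec.valid:
            continue
        level = level_map.get((rec.chrom, rec.start, rec.end))
        if level is None:
            continue
        n_joined += 1
        all_scores.append(rec.score)
        if hyper_range[0] <= level <= hyper_range[1]:
            hyper_scores.append(rec.score)
        elif hypo_range[0] <= level <= hypo_range[1]:
            hypo_scores.append(rec.score)
        else:
            n_unassigned += 1
    if n_joined == 0:
        raise ValueError("no windows matched the methylation-level table")

    def _hist(scores):
        if not scores:  # an empty stratum is a valid (all-zero) histogram
            from .cpg_metrics import HISTOGRAM_TOP

            n_bins = int(round(HISTOGRAM_TOP / bin_width))
            return ScoreHistogram(
                bin_width=bin_width, counts=np.zeros(n_bins, dtype=np.int64), n_windows=0
            )
        return ScoreHistogram.from_scores(np.asarray(scores), bin_width=bin_width)

    return StratifiedHistograms(
        all=_hist(all_scores),
        hyper=_hist(hyper_scores),
        hypo=_hist(hypo_scores),
        n_unassigned=n_unassigned,
    )
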