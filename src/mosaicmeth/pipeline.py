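"""End-to-end per-genome workflow.

``run_genome`` chains the whole method: fixed 2-kb window scores ->
genome-wide histogram -> compulsory two-Gaussian fit -> barycenter
boundary -> sliding 2-kb/100-bp window scores -> classification ->
100-bp binary track -> 2-kb majority smoothing -> segments -> length
statistics and the two ratio indices. ``run_compare`` tabulates the
indices for several genomes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .cpg_metrics import (
    AMBIGUITY_MAX,
    DEFAULT_BIN_WIDTH,
    build_histogram,
    window_scores,
    windows_to_frame,
)
from .genome_io import read_fasta
from .mixture_model import fit_two_gaussians
from .segmentation import (
    classify_windows,
    extract_segments,
    project_to_bins,
    segment_statistics,
    smooth_track,
    write_segments_bed,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_genome", "run_compare"]


@dataclass
class RunConfig:
    """Tunable parameters of the per-genome analysis (field defaults are
    the standard ones: 2-kb windows, 100-bp step, 50-ambiguous-base
    filter, 0.02 score bins, weighted barycenter, 2-kb smoothing)."""

    window_width: int = 2000
    step: int = 100
    bin_width: float = DEFAULT_BIN_WIDTH
    ambiguity_max: int = AMBIGUITY_MAX
    barycenter_mode: str = "weighted"  # or "midpoint"
    tie: str = "unmeth"  # label at score exactly equal to the boundary
    placement: str = "midpoint"  # window-label projection target bin
    smooth_window: int = 2000
    sd_ddof: int = 0  # population SD of segment lengths

    def validate(self) -> None:
        if min(self.window_width, self.step, self.smooth_window) <= 0:
            raise ValueError("window sizes and step must be positive")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.ambiguity_max < 0:
            raise ValueError("ambiguity_max must be non-negative")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_genome(fasta, config: Optional[RunConfig] = None, out_dir=None):
    """Run the full analysis on one genome FASTA.

    Returns a dict with the fit, segments, indices and score records.
    With ``out_dir`` set, writes indices.json, segments.bed,
    histogram.tsv, fit.json, windows_fixed.tsv, windows_sliding.tsv and
    a manifest.json recording the configuration, package version and
    artifact checksums; on a stage failure the partial outputs are
    removed and the error names the stage.
    """
    config = config or RunConfig()
    config.validate()
    out_dir = Path(out_dir) if out_dir is not None else None
    written: list[Path] = []
    stage = "read_fasta"
    try:
        genome = read_fasta(fasta) if not isinstance(fasta, list) else fasta

        stage = "window_scores(fixed)"
        fixed = window_scores(
            genome, mode="fixed", width=config.window_width, ambiguity_max=config.ambiguity_max
        )
        n_invalid = sum(not r.valid for r in fixed)
        logger.info(
            "fixed windows: %d total, %d discarded by the ambiguity/definedness filter",
            len(fixed),
            n_invalid,
        )
        if not any(r.valid for r in fixed):
            raise ValueError("no scorable windows")

        stage = "build_histogram"
        hist = build_histogram(fixed, bin_width=config.bin_width)

        stage = "fit_two_gaussians"
        fit = fit_two_gaussians(hist, barycenter_mode=config.barycenter_mode)
        boundary = fit.boundary

        stage = "window_scores(sliding)"
        sliding = window_scores(
            genome,
            mode="sliding",
            width=config.window_width,
            step=config.step,
            ambiguity_max=config.ambiguity_max,
        )

        stage = "segmentation"
        segments = []
        by_chrom: dict[str, list] = {}
        for rec in sliding:
            by_chrom.setdefault(rec.chrom, []).append(rec)
        lengths = {seq.name: len(seq) for seq in genome}
        for chrom, recs in by_chrom.items():
            labels = classify_windows(recs, boundary, tie=config.tie)
            track = project_to_bins(
                recs, labels, lengths[chrom], placement=config.placement
            )
            smoothed = smooth_track(track, window=config.smooth_window)
            segments.extend(extract_segments(smoothed))

        stage = "segment_statistics"
        indices = segment_statistics(segments, boundary, ddof=config.sd_ddof)
        logger.info(
            "segments: %d methylated, %d unmethylated; boundary %.3f",
            indices.n_meth_segments,
            indices.n_unmeth_segments,
            boundary,
        )

        if out_dir is not None:
            stage = "write_outputs"
            out_dir.mkdir(parents=True, exist_ok=True)

            def _out(name: str) -> Path:
                p = out_dir / name
                written.append(p)
                return p

            windows_to_frame(fixed).to_csv(
                _out("windows_fixed.tsv"), sep="\t", index=False, float_format="%.6g"
            )
            windows_to_frame(sliding).to_csv(
                _out("windows_sliding.tsv"), sep="\t", index=False, float_format="%.6g"
            )
            hist.write_tsv(_out("histogram.tsv"))
            fit.to_json(_out("fit.json"))
            write_segments_bed(_out("segments.bed"), segments)
            indices.to_json(_out("indices.json"))
            manifest = {
                "package": "mosaicmeth",
                "version": __version__,
                "config": asdict(config),
                "inputs": {"fasta": str(fasta)},
                "artifacts": {p.name: _file_sha256(p) for p in written},
            }
            with open(out_dir / "manifest.json", "wt") as fh:
                json.dump(manifest, fh, indent=2, sort_keys=True)
                fh.write("\n")
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, StageError):
            raise
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    return {
        "fit": fit,
        "boundary": boundary,
        "segments": segments,
        "indices": indices,
        "histogram": hist,
        "fixed_windows": fixed,
        "sliding_windows": sliding,
    }


def run_compare(fastas: Sequence, config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Indices for several genomes, one row each, in the given order.

    A per-genome failure yields a row with an ``error`` column filled;
    the remaining genomes still run.
    """
    if not fastas:
        raise ValueError("at least one genome required")
    rows = []
    for fasta in fastas:
        name = Path(str(fasta)).name
        try:
            res = run_genome(fasta, config=config)
            row = {"genome": name, **res["indices"].to_dict(), "error": ""}
        except Exception as exc:  # noqa: BLE001 - reported per genome
            logger.error("genome %s failed: %s", name, exc)
            row = {"genome": name, "error": str(exc)}
        rows.append(row)
    return pd.DataFrame(rows)
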