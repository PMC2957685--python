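# Methods

## Model and procedure

The analysis rests on one biological regularity: methylated cytosines in CpG
context deaminate to thymine at an elevated rate, so genomic tracts that have
been stably methylated over evolutionary time are depleted of CpG
dinucleotides, while stably unmethylated tracts retain them. The pipeline
turns that signal into a per-genome summary in five steps.

1. **Window scores.** Each sequence record is tiled with non-overlapping 2-kb
   windows. A window's CpG score is `n_CpG * L / (n_C * n_G)` with `L = 2000`
   the full window width. CpG dinucleotides are counted strictly inside the
   window (pairs spanning a window edge are ignored; this perturbs adjacent
   windows by at most one count). Counting is case-insensitive, so
   soft-masked (lowercase) sequence is treated as ordinary sequence; any
   non-ACGT residue counts as ambiguous and can participate in no CpG. A
   window is discarded when it contains more than 50 ambiguous bases (exactly
   50 is kept) or when `n_C * n_G = 0`, which leaves the score undefined.
   Windows restart at coordinate 0 on every record, and trailing fragments
   shorter than 2 kb are dropped rather than padded.

2. **Histogram.** Valid fixed-window scores are binned at width 0.02 over
   [0, 2.0); scores at or above 2.0 accumulate in the final bin. About 100
   bins resolve both modes of a bimodal score distribution while keeping
   dozens to thousands of counts per occupied bin in genomes of a few Mb and
   up.

3. **Two-Gaussian decomposition.** The histogram is decomposed into exactly
   two normal components by expectation-maximisation on the grouped data:
   bin midpoints are the observations, bin counts their multiplicities. The
   fit is therefore invariant to rescaling all counts by a constant, and
   fitting the bin *midpoint* rather than the bin integral costs O(bin
   width^2) accuracy, negligible at 0.02. The decomposition is compulsory —
   two components are always returned — because in globally methylated
   genomes the unmethylated fraction is a small bump on the right shoulder of
   a seemingly unimodal distribution, not a separate mode.

   Initialisation is deterministic: the distribution is split at its
   weighted median, each half supplying one component's initial mean and SD,
   with weights 0.5/0.5. This makes every run reproducible without a seed.
   Convergence is declared when the relative log-likelihood change falls
   below 1e-8 (at most 2000 iterations); the log-likelihood is checked to be
   non-decreasing at every step. A variance floor of 1e-6 (score units
   squared) prevents a component collapsing onto a single bin; if a
   component's weight nevertheless falls below 1e-4 the fit is flagged
   non-converged and the last parameters are returned. An EM on raw
   (unbinned) scores is provided as a cross-check path.

4. **Boundary.** The decision threshold between methylated-like and
   unmethylated-like windows is the *barycenter* of the decomposition: the
   mixing-weight weighted mean of the two component means,
   `w_lo*mu_lo + w_hi*mu_hi` — the literal center of mass of the fitted
   density, which always lies between the two means. An unweighted midpoint
   `(mu_lo + mu_hi)/2` is available behind `barycenter_mode="midpoint"` for
   sensitivity analysis; the weighted form is the default because it is the
   center of mass of the decomposition and adapts to unbalanced mixtures.
   Being fitted per species, the boundary needs no fixed universal CpG-score
   cutoff and transfers across genomes with different G+C and CpG content.

5. **Segmentation and indices.** Sliding 2-kb windows at 100-bp steps are
   classified: score below the boundary is methylated, above is
   unmethylated; a score exactly at the boundary is labelled unmethylated (a
   measure-zero tie on real data; configurable). Each window's label is
   written to the single 100-bp bin containing the window midpoint — a
   symmetric choice that phases the track with window centers; projecting to
   the start bin is available behind a flag. Bins no window center reaches
   (chromosome ends, runs of discarded gap windows) are no-data. The track
   is smoothed by a majority vote over the 20 bins centered on each bin;
   exact 10–10 ties carry the previous (left) smoothed label, or the bin's
   own label at a chromosome start — a hysteresis rule that is deterministic
   and cannot oscillate. No-data bins stay no-data, never vote, and split
   segments rather than letting them bridge assembly gaps. Maximal constant
   runs become segments; per-status means and standard deviations of the
   segment lengths yield the indices: `ratio_lengths = mean_U / mean_M` and
   `ratio_sds = sd_U / sd_M`. SDs are population-style (divide by n; with
   thousands of segments the sample-SD alternative, exposed as `sd_ddof=1`,
   changes nothing material). No minimum-segment-length filter is applied.
   In the degenerate case where both classes have zero length-SD the SD
   ratio is reported as 1 (equal scatter); if one status class is absent
   both ratios are undefined (NaN) and a warning is issued.

Multi-record assemblies are handled per scaffold (windows and segments never
span record boundaries) and the per-record histograms are pooled genome-wide
before fitting, so one boundary serves the whole genome.

## Validation by measured methylation

Where per-window methylation levels exist, windows with mean level in
[0.7, 1.0] are called hypermethylated and [0, 0.3] hypomethylated (both
endpoints closed; levels may be given as fractions or percentages via a
declared dialect — 1.0 is ambiguous, so nothing is auto-detected; binary 1/0
status tables are read as levels 1.0/0.0). Levels join to windows by exact
(chrom, start, end). If the CpG score separates methylation states, the two
strata form well-separated bell-shaped score histograms — the empirical
justification for the two-component model.

## The synthetic generator

`generate_mosaic_genome` emulates exactly the structure the method assumes:
alternating methylated/unmethylated tracts with gamma-distributed lengths
(shape 1.2, so the length SD is of the same order as the mean, as in real
segment tables; means default to 5 kb / 6.5 kb), per-state target CpG o/e
(defaults 0.25 / 1.0, the scale observed in methylated vs unmethylated
sequence), G+C content 0.42, and optional N-runs at a configurable expected
genome fraction. Within a tract, sequence is drawn from a first-order Markov
chain over ACGT. The transition matrix is derived from the dinucleotide
joint distribution obtained by iterative proportional fitting with the CG
cell pinned at `oe * p_C * p_G`: both marginals equal the requested base
composition, so that composition is exactly stationary and the expected
window-level o/e equals the target up to an (L-1)/L edge factor. I.i.d. base
drawing cannot do this — o/e is a dinucleotide property. Targets above the
joint-distribution ceiling `min(p_C, p_G)/(p_C p_G)` are rejected as
infeasible.

What the generator does *not* emulate: repeats and transposons, isochore
G+C variation, CpG-island fine structure, per-tract o/e heterogeneity, and
sequencing/assembly error. Tests passing on synthetic genomes therefore
demonstrate that the pipeline recovers the two-state tract structure it
models, not that any particular real genome satisfies that model.

On the default 10-Mb configuration the pipeline recovers the tract-length
ratio within 20% (the smoothing step erases tracts much shorter than 2 kb
in both classes, which biases both means upward and partially cancels in
the ratio) and labels over 90% of covered 100-bp bins correctly; residual
disagreement concentrates at tract boundaries, where 2-kb windows straddle
states.

## Problem sizes and numerical choices

The test suite exercises the full pipeline at 0.4–10 Mb and the mixture fit
at 20,000–50,000 draws; these sizes give stable estimates (segment counts in
the hundreds to thousands, occupied histogram bins with large counts) while
keeping the default suite fast. Larger genomes change nothing
algorithmically — every stage is linear in sequence length.

Other conventions: 0-based half-open coordinates everywhere, including all
BED output; deterministic end-to-end (identical input and configuration give
bit-identical outputs, recorded as artifact checksums in a run manifest);
all randomness in the synthetic module flows from a single integer seed to a
`numpy` Generator.

## Limitations

The method estimates the genome-wide *proportion and granularity* of
methylated versus unmethylated sequence; it does not predict the methylation
status or level of any specific region, and tissue- or stage-specific
methylation is invisible to it. The CpG-score signal presumes long-term
evolutionary stability of the pattern; recently changed regions, heavily
methylated CpG islands and unmethylated CpG-poor tracts are misassigned by
construction. Results on low-coverage or gap-rich assemblies are degraded
because gap-spanning windows are discarded and segments cannot cross them.
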