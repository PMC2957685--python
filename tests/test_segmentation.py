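import math

import numpy as np
import pytest

from mosaicmeth.cpg_metrics import WindowRecord
from mosaicmeth.segmentation import (
    LABEL_METH,
    LABEL_NO_DATA,
    LABEL_UNMETH,
    BinaryTrack,
    MethylationSegment,
    classify_windows,
    extract_segments,
    length_ratio_indices,
    project_to_bins,
    segment_statistics,
    smooth_track,
)


def win(start, score, valid=True, chrom="c"):
    return WindowRecord(chrom, start, start + 2000, 400, 400, 10, 0, score, valid)


def seg(length, status, start=0):
    return MethylationSegment("c", start, start + length, status)


# ---------------------------------------------------------------- oracles


def oracle_smooth(labels, half=10):
    """Brute-force centered-majority smoothing with left-carry ties."""
    n = len(labels)
    out = [LABEL_NO_DATA] * n
    prev = LABEL_NO_DATA
    for i in range(n):
        if labels[i] == LABEL_NO_DATA:
            prev = LABEL_NO_DATA
            continue
        window = labels[max(0, i - half) : min(n, i + half)]
        m = sum(1 for x in window if x == LABEL_METH)
        u = sum(1 for x in window if x == LABEL_UNMETH)
        if m > u:
            out[i] = LABEL_METH
        elif u > m:
            out[i] = LABEL_UNMETH
        else:
            out[i] = prev if prev != LABEL_NO_DATA else labels[i]
        prev = out[i]
    return out


def oracle_rle(labels, bin_size=100, chrom="c"):
    """Independent run-length encoding into segments."""
    segments = []
    run_start = None
    run_label = LABEL_NO_DATA
    for i, lab in enumerate(list(labels) + [None]):
        if lab != run_label:
            if run_label in (LABEL_METH, LABEL_UNMETH):
                segments.append(
                    MethylationSegment(
                        chrom,
                        run_start * bin_size,
                        i * bin_size,
                        "M" if run_label == LABEL_METH else "U",
                    )
                )
            run_start, run_label = i, lab
    return segments


# ----------------------------------------------------------------- tests


class TestClassify:
    def test_decision_rule(self):
        records = [win(0, 0.5), win(100, 0.9), win(200, 0.721), win(300, 0.3, valid=False)]
        labels = classify_windows(records, boundary=0.721)
        assert list(labels) == [LABEL_METH, LABEL_UNMETH, LABEL_UNMETH, LABEL_NO_DATA]

    def test_tie_rule_configurable(self):
        (lab,) = classify_windows([win(0, 0.7)], boundary=0.7, tie="meth")
        assert lab == LABEL_METH

    def test_nonpositive_boundary_errors(self):
        with pytest.raises(ValueError):
            classify_windows([win(0, 0.5)], boundary=0.0)


class TestProject:
    def test_single_window_lands_in_midpoint_bin(self):
        track = project_to_bins([win(0, 0.2)], np.array([LABEL_METH]), chrom_length=3000)
        assert track.n_bins == 30
        assert track.labels[10] == LABEL_METH  # bin covering [1000, 1100)
        assert (np.delete(track.labels, 10) == LABEL_NO_DATA).all()

    def test_start_placement_option(self):
        track = project_to_bins(
            [win(500, 0.2)], np.array([LABEL_METH]), chrom_length=3000, placement="start"
        )
        assert track.labels[5] == LABEL_METH

    def test_alternating_labels_match_enumeration(self):
        starts = list(range(0, 2001, 100))
        records = [win(s, 0.2) for s in starts]
        labels = np.array([LABEL_METH if i % 2 == 0 else LABEL_UNMETH for i in range(len(starts))])
        track = project_to_bins(records, labels, chrom_length=4100)
        expected = np.full(41, LABEL_NO_DATA, dtype=np.int8)
        for s, lab in zip(starts, labels):
            expected[(s + 1000) // 100] = lab  # hand projection to midpoint bins
        assert np.array_equal(track.labels, expected)

    def test_mixed_chromosomes_error(self):
        with pytest.raises(ValueError, match="multiple chromosomes"):
            project_to_bins(
                [win(0, 0.2, chrom="a"), win(0, 0.2, chrom="b")],
                np.array([LABEL_METH, LABEL_METH]),
                chrom_length=3000,
            )


def track_of(labels):
    return BinaryTrack(chrom="c", bin_size=100, labels=np.asarray(labels, dtype=np.int8))


class TestSmooth:
    def test_singleton_flip_absorbed(self):
        labels = [LABEL_METH] * 30
        labels[15] = LABEL_UNMETH
        out = smooth_track(track_of(labels))
        assert (out.labels == LABEL_METH).all()

    def test_uniform_track_unchanged(self):
        labels = [LABEL_UNMETH] * 25
        out = smooth_track(track_of(labels))
        assert np.array_equal(out.labels, track_of(labels).labels)

    def test_no_data_preserved_and_excluded(self):
        labels = [LABEL_METH] * 10 + [LABEL_NO_DATA] * 5 + [LABEL_METH] * 10
        out = smooth_track(track_of(labels))
        assert (out.labels[10:15] == LABEL_NO_DATA).all()
        assert (out.labels[:10] == LABEL_METH).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_track_matches_bruteforce_majority(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.choice(
            [LABEL_NO_DATA, LABEL_METH, LABEL_UNMETH], size=200, p=[0.1, 0.45, 0.45]
        )
        out = smooth_track(track_of(labels))
        assert list(out.labels) == oracle_smooth(list(labels))

    def test_window_not_multiple_of_bin_errors(self):
        with pytest.raises(ValueError):
            smooth_track(track_of([LABEL_METH] * 10), window=250)


class TestExtract:
    def test_run_length_example(self):
        segs = extract_segments(
            track_of([LABEL_METH, LABEL_METH, LABEL_UNMETH, LABEL_UNMETH, LABEL_UNMETH])
        )
        assert segs == [
            MethylationSegment("c", 0, 200, "M"),
            MethylationSegment("c", 200, 500, "U"),
        ]

    def test_all_no_data_empty(self):
        assert extract_segments(track_of([LABEL_NO_DATA] * 10)) == []

    def test_no_data_splits_runs(self):
        segs = extract_segments(
            track_of([LABEL_METH] * 3 + [LABEL_NO_DATA] + [LABEL_METH] * 2)
        )
        assert [(s.start, s.end) for s in segs] == [(0, 300), (400, 600)]

    @pytest.mark.parametrize("seed", [3, 4])
    def test_random_track_matches_rle_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.choice([LABEL_NO_DATA, LABEL_METH, LABEL_UNMETH], size=500)
        assert extract_segments(track_of(labels)) == oracle_rle(labels)


class TestStatistics:
    def test_ratio_index_arithmetic(self):
        ratio_lengths, ratio_sds = length_ratio_indices(5314.6, 5570.8, 6785.9, 9550.2)
        assert ratio_lengths == pytest.approx(6785.9 / 5314.6)
        assert ratio_sds == pytest.approx(9550.2 / 5570.8)

    def test_equal_lengths_give_unit_ratios_and_zero_sds(self):
        segments = [seg(3000, "M", 0), seg(3000, "M", 4000), seg(3000, "U", 8000), seg(3000, "U", 12000)]
        idx = segment_statistics(segments, boundary=0.5)
        assert idx.ratio_lengths == pytest.approx(1.0)
        assert idx.meth_sd == 0.0 and idx.unmeth_sd == 0.0
        assert idx.ratio_sds == pytest.approx(1.0)  # equal (zero) scatter in both classes
        assert idx.n_meth_segments == idx.n_unmeth_segments == 2

    def test_population_vs_sample_sd(self):
        segments = [seg(1000, "M", 0), seg(3000, "M", 2000), seg(2000, "U", 6000), seg(6000, "U", 9000)]
        pop = segment_statistics(segments, boundary=0.5, ddof=0)
        samp = segment_statistics(segments, boundary=0.5, ddof=1)
        assert pop.meth_sd == pytest.approx(1000.0)
        assert samp.meth_sd == pytest.approx(1000.0 * math.sqrt(2))
        # the SD ratio is invariant here because both classes scale alike
        assert pop.ratio_sds == pytest.approx(samp.ratio_sds)

    def test_empty_class_warns_with_nan_ratios(self):
        with pytest.warns(RuntimeWarning, match="no segments"):
            idx = segment_statistics([seg(1000, "M")], boundary=0.5)
        assert math.isnan(idx.ratio_lengths) and math.isnan(idx.ratio_sds)
        assert idx.n_unmeth_segments == 0

    def test_segment_invariants_on_random_track(self):
        rng = np.random.default_rng(9)
        labels = rng.choice([LABEL_NO_DATA, LABEL_METH, LABEL_UNMETH], size=800)
        segs = extract_segments(smooth_track(track_of(labels)))
        for a, b in zip(segs, segs[1:]):
            assert a.end <= b.start  # non-overlapping, ordered
        assert all(s.length % 100 == 0 and s.length > 0 for s in segs)
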