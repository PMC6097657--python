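import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_track, random_transcripts
from lncland.formats import CoverageTrack, Transcript
from lncland.segment import (Segment, SegmentationParams, call_segments,
                             coverage_metrics, filter_length, make_grid,
                             merge_segments, optimize_parameters,
                             pool_coverage, segment_track,
                             single_sample_retention, subtract_annotation,
                             validate_candidates)
from oracles import brute_pct_covered, brute_segment

P = SegmentationParams()


def seg(start, end, density, chrom="chr1", strand="+"):
    return Segment(chrom, strand, start, end, total_hits=density * (end - start))


class TestPool:
    def test_single_track_identity(self):
        t = CoverageTrack("chr1", "+", [1.0, 2.0, 3.0])
        assert np.array_equal(pool_coverage([t]).density, t.density)

    def test_per_base_sum(self):
        a = CoverageTrack("chr1", "+", [1.0, 2.0])
        b = CoverageTrack("chr1", "+", [3.0, 4.0])
        assert list(pool_coverage([a, b]).density) == [4.0, 6.0]

    def test_order_invariance(self, rng):
        tracks = [CoverageTrack("chr1", "+", rng.poisson(5, 100).astype(float))
                  for _ in range(6)]
        ref = pool_coverage(tracks).density
        for _ in range(5):
            perm = rng.permutation(len(tracks))
            assert np.array_equal(
                pool_coverage([tracks[i] for i in perm]).density, ref)

    def test_length_mismatch_rejected(self):
        a = CoverageTrack("chr1", "+", [1.0])
        b = CoverageTrack("chr1", "+", [1.0, 2.0])
        with pytest.raises(ValueError, match="mismatch"):
            pool_coverage([a, b])


class TestCallSegments:
    def test_all_zero_track(self):
        assert call_segments(CoverageTrack("chr1", "+", np.zeros(50)), P) == []

    def test_single_run_with_mean_density(self):
        track = CoverageTrack("chr1", "+", [0, 12, 12, 12, 0])
        (s,) = call_segments(track, P)
        assert (s.start, s.end, s.mean_density) == (1, 4, 12.0)

    def test_cutoff_is_strict(self):
        track = CoverageTrack("chr1", "+", np.full(30, 10.0))
        assert call_segments(track, P) == []


class TestMerge:
    def test_far_apart_unchanged(self):
        segs = [seg(0, 100, 20), seg(250, 300, 25)]
        assert merge_segments(segs, P) == segs

    def test_close_and_similar_merged(self):
        merged = merge_segments([seg(0, 100, 20), seg(150, 250, 30)], P)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (0, 250)
        # density recomputed over the whole span including the gap
        assert merged[0].mean_density == pytest.approx(
            (20 * 100 + 30 * 100) / 250)

    def test_close_but_discordant_not_merged(self):
        segs = [seg(0, 100, 10), seg(150, 250, 200)]
        assert merge_segments(segs, P) == segs

    def test_fold_rule_can_be_disabled(self):
        segs = [seg(0, 100, 10), seg(150, 250, 200)]
        loose = SegmentationParams(fold_rule_enabled=False)
        assert len(merge_segments(segs, loose)) == 1

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            merge_segments([seg(100, 200, 5), seg(0, 90, 5)], P)

    def test_merged_density_used_for_next_comparison(self):
        # A+B fuse (gap 80, fold 1.5) into [0, 280) at density 17.9 — lower
        # than B's own 30.  C at density 200 would pass the fold rule against
        # B alone (6.7x) but fails it against the recomputed merged density
        # (11.2x), so it must stay separate.
        segs = [seg(0, 100, 20), seg(180, 280, 30), seg(340, 440, 200)]
        merged = merge_segments(segs, P)
        assert [(s.start, s.end) for s in merged] == [(0, 280), (340, 440)]
        assert merged[0].mean_density == pytest.approx(5000 / 280)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(
    st.tuples(st.integers(1, 300), st.integers(1, 300),
              st.floats(0.5, 500.0)),
    min_size=0, max_size=12,
))
def test_merge_conserves_hits_and_keeps_segments_disjoint(pieces):
    """Merging preserves total hits, never decreases covered span, and
    always yields sorted, non-overlapping segments."""
    segs, pos = [], 0
    for gap, width, density in pieces:
        start = pos + gap
        segs.append(seg(start, start + width, density))
        pos = start + width
    merged = merge_segments(segs, P)
    assert sum(s.total_hits for s in merged) == pytest.approx(
        sum(s.total_hits for s in segs))
    assert sum(s.length for s in merged) >= sum(s.length for s in segs)
    for a, b in zip(merged, merged[1:]):
        assert a.end <= b.start


class TestSubtractAndFilter:
    def test_opposite_strand_overlap_retained(self):
        ann = [Transcript("m", "chr1", "-", 0, 500, "mRNA")]
        segs = [seg(100, 400, 20)]
        assert subtract_annotation(segs, ann) == segs

    def test_single_base_same_strand_overlap_removed(self):
        ann = [Transcript("m", "chr1", "+", 399, 500, "mRNA")]
        assert subtract_annotation([seg(100, 400, 20)], ann) == []

    def test_no_annotation_is_identity(self):
        segs = [seg(0, 300, 15)]
        assert subtract_annotation(segs, []) == segs

    def test_length_boundary(self):
        assert filter_length([seg(0, 200, 15)], P) == []
        assert filter_length([seg(0, 201, 15)], P) == [seg(0, 201, 15)]


class TestEndToEndOracle:
    def test_matches_brute_force_on_random_tracks(self, rng):
        """pool->call->merge->subtract->filter equals the naive per-base
        reference on random tracks with random annotations."""
        for i in range(30):
            length = int(rng.integers(500, 5000))
            tracks = [random_track(rng, length) for _ in range(3)]
            ann = random_transcripts(rng, int(rng.integers(0, 6)), length,
                                     prefix="m")
            pooled = pool_coverage(tracks)
            got = segment_track(pooled, P, ann)
            same_strand = [(t.start, t.end) for t in ann if t.strand == "+"]
            expected = brute_segment(
                pooled.density, P.density_cutoff, P.max_gap, P.max_fold,
                P.fold_rule_enabled, P.min_length, same_strand)
            assert [(s.start, s.end) for s in got] == \
                [(e[0], e[1]) for e in expected]
            for s, e in zip(got, expected):
                assert s.total_hits == pytest.approx(e[2])

    def test_output_segments_never_overlap(self, rng):
        for _ in range(10):
            track = random_track(rng, 3000)
            segs = segment_track(track, P)
            for a, b in zip(segs, segs[1:]):
                assert a.end <= b.start

    def test_merging_never_decreases_total_span(self, rng):
        for _ in range(10):
            track = random_track(rng, 3000)
            raw = call_segments(track, P)
            merged = merge_segments(raw, P)
            raw_span = sum(s.length for s in raw)
            merged_span = sum(s.length for s in merged)
            assert merged_span >= raw_span

    def test_subtraction_only_removes(self, rng):
        for _ in range(10):
            track = random_track(rng, 3000)
            ann = random_transcripts(rng, 4, 3000, prefix="m")
            merged = merge_segments(call_segments(track, P), P)
            kept = subtract_annotation(merged, ann)
            assert set(kept) <= set(merged)


class TestCoverageMetrics:
    def test_identical_interval_gives_100_both_ways(self):
        ref = [Transcript("l", "chr1", "+", 100, 400, "lncRNA")]
        m = coverage_metrics([seg(100, 400, 20)], ref)
        assert m["per_lncrna_pct"]["l"] == 100.0
        assert m["per_segment_pct"] == [100.0]

    def test_disjoint_sets_give_zero(self):
        ref = [Transcript("l", "chr1", "+", 1000, 1300, "lncRNA")]
        m = coverage_metrics([seg(0, 300, 20)], ref)
        assert m["mean_lncrna_coverage_pct"] == 0.0
        assert m["mean_segment_precision_pct"] == 0.0

    def test_matches_base_level_brute_force(self, rng):
        for _ in range(20):
            refs = random_transcripts(rng, 5, 4000, prefix="l")
            segs = [seg(int(s), int(s) + int(w), 20.0,
                        strand="+" if rng.random() < 0.5 else "-")
                    for s, w in zip(rng.integers(0, 3500, 5),
                                    rng.integers(50, 500, 5))]
            m = coverage_metrics(segs, refs)
            for t in refs:
                intervals = [(s.start, s.end) for s in segs
                             if s.strand == t.strand]
                assert m["per_lncrna_pct"][t.id] == pytest.approx(
                    brute_pct_covered(t.start, t.end, intervals))

    def test_symmetric_as_plain_interval_sets(self, rng):
        refs = random_transcripts(rng, 5, 4000, prefix="l")
        segs = [seg(t.start, t.end, 20.0, strand=t.strand)
                for t in random_transcripts(rng, 5, 4000, prefix="x")]
        m1 = coverage_metrics(segs, refs)
        swapped_refs = [Transcript(f"s{i}", s.chromosome, s.strand, s.start,
                                   s.end, "lncRNA")
                        for i, s in enumerate(segs)]
        swapped_segs = [seg(t.start, t.end, 1.0, strand=t.strand)
                        for t in refs]
        m2 = coverage_metrics(swapped_segs, swapped_refs)
        assert m1["mean_lncrna_coverage_pct"] == pytest.approx(
            m2["mean_segment_precision_pct"])


class TestOptimizer:
    def make_coverage(self, rng, signal=50.0, background=2.0):
        """Two samples; one planted transcript on each strand."""
        coverage = {}
        refs = [Transcript("l1", "chr1", "+", 1000, 1500, "lncRNA"),
                Transcript("l2", "chr1", "-", 2500, 3200, "lncRNA")]
        for sample in ("a", "b"):
            tracks = {}
            for strand in "+-":
                density = rng.poisson(background, 5000).astype(float)
                for t in refs:
                    if t.strand == strand:
                        density[t.start:t.end] += rng.poisson(
                            signal, t.length)
                tracks[strand] = CoverageTrack("chr1", strand, density)
            coverage[sample] = {"chr1": (tracks["+"], tracks["-"])}
        return coverage, refs

    def test_single_point_grid_returned(self, rng):
        coverage, refs = self.make_coverage(rng)
        grid = [SegmentationParams(density_cutoff=30)]
        table, best = optimize_parameters(coverage, refs, grid)
        assert best == grid[0] and len(table) == 1

    def test_chosen_cutoff_separates_background_from_signal(self, rng):
        coverage, refs = self.make_coverage(rng, signal=50, background=2)
        grid = make_grid(density_cutoffs=(1.0, 4.0, 20.0, 60.0, 150.0))
        _, best = optimize_parameters(coverage, refs, grid)
        # pooled background ~4, pooled signal ~104
        assert 4.0 < best.density_cutoff < 104.0

    def test_reported_metrics_match_standalone_run(self, rng):
        coverage, refs = self.make_coverage(rng)
        grid = make_grid(density_cutoffs=(20.0, 60.0))
        table, best = optimize_parameters(coverage, refs, grid)
        from lncland.segment import segment_genome
        segs = segment_genome(coverage, best)
        fresh = coverage_metrics(segs, refs)
        row = table.loc[table["density_cutoff"] == best.density_cutoff].iloc[0]
        assert row["lncrna_coverage_pct"] == pytest.approx(
            fresh["mean_lncrna_coverage_pct"])
        assert row["segment_precision_pct"] == pytest.approx(
            fresh["mean_segment_precision_pct"])

    def test_empty_grid_rejected(self, rng):
        coverage, refs = self.make_coverage(rng)
        with pytest.raises(ValueError, match="nonempty"):
            optimize_parameters(coverage, refs, [])


class TestValidation:
    def test_identical_feature_is_validated(self):
        cand = [seg(100, 400, 20)]
        ext = [Transcript("x", "chr1", "+", 100, 400, "lncRNA")]
        tracks = {("chr1", "+"): CoverageTrack("chr1", "+", np.full(500, 20.0)),
                  ("chr1", "-"): CoverageTrack("chr1", "-", np.zeros(500))}
        report = validate_candidates(cand, ext, tracks)
        assert report.loc["x", "validated"]
        assert not report.loc["x", "leak_through"]

    def test_leak_through_flagged(self):
        ext = [Transcript("x", "chr1", "+", 100, 400, "lncRNA")]
        tracks = {("chr1", "+"): CoverageTrack("chr1", "+", np.zeros(500)),
                  ("chr1", "-"): CoverageTrack("chr1", "-", np.full(500, 50.0))}
        report = validate_candidates([], ext, tracks)
        assert not report.loc["x", "validated"]
        assert report.loc["x", "leak_through"]

    def test_counts_match_brute_force(self, rng):
        for _ in range(10):
            ext = random_transcripts(rng, 8, 3000, prefix="x")
            cands = [seg(int(s), int(s) + int(w), 30.0,
                         strand="+" if rng.random() < 0.5 else "-")
                     for s, w in zip(rng.integers(0, 2500, 4),
                                     rng.integers(100, 400, 4))]
            tracks = {(c, st): CoverageTrack(c, st,
                                             rng.poisson(3, 3000).astype(float))
                      for c in ("chr1",) for st in "+-"}
            report = validate_candidates(cands, ext, tracks)
            for t in ext:
                expected = any(
                    c.strand == t.strand
                    and min(c.end, t.end) > max(c.start, t.start)
                    for c in cands)
                assert report.loc[t.id, "validated"] == expected


class TestSingleSampleRetention:
    def test_single_sample_is_trivially_retained(self, rng):
        track = random_track(rng, 2000)
        coverage = {"only": {"chr1": (track, CoverageTrack("chr1", "-",
                                                           np.zeros(2000)))}}
        pooled = segment_track(track, P)
        assert single_sample_retention(coverage, pooled, P) == 1.0

    def test_signal_in_one_sample_retains_candidate(self):
        quiet = np.zeros(1000)
        loud = np.zeros(1000)
        loud[200:500] = 40.0
        coverage = {
            "s1": {"chr1": (CoverageTrack("chr1", "+", loud),
                            CoverageTrack("chr1", "-", quiet))},
            "s2": {"chr1": (CoverageTrack("chr1", "+", quiet),
                            CoverageTrack("chr1", "-", quiet))},
        }
        pooled = [seg(200, 500, 40.0)]
        assert single_sample_retention(coverage, pooled, P) == 1.0
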