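"""Interval model, BED round-trips and the peak specificity filters."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caplocus.intervals import (
    BedParseError,
    GenomicInterval,
    IntervalSet,
    blacklist_filter,
    overlaps,
    read_bed,
    replicate_intersection,
    specificity_pipeline,
    subtract_control,
    tn5_offset,
    write_bed,
)
from caplocus.synthetic_data import simulate_capture_peaks

from conftest import brute_force_overlaps, random_interval_set


def iv(chrom, start, end, **kw):
    return GenomicInterval(chrom, start, end, **kw)


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "chrom,start,end",
        [("chr1", -1, 10), ("chr1", 10, 10), ("chr1", 200, 100), ("", 0, 10)],
    )
    def test_invalid_intervals_rejected(self, chrom, start, end):
        with pytest.raises(ValueError):
            GenomicInterval(chrom, start, end)

    def test_length_is_half_open_span(self):
        assert len(iv("chr1", 100, 200)) == 100


class TestBedIO:
    def test_minimal_bed3_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        s = read_bed(p)
        assert list(s) == [iv("chr1", 100, 200)]

    def test_empty_file_gives_empty_set(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert read_bed(p).size() == 0

    def test_track_and_comment_lines_skipped(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("track name=peaks\n# comment\nchr1\t0\t10\n")
        assert read_bed(p).size() == 1

    def test_bed6_fields_populated(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tpeak1\t7.5\t-\n")
        (rec,) = read_bed(p)
        assert (rec.name, rec.score, rec.strand) == ("peak1", 7.5, "-")

    @pytest.mark.parametrize("line", ["chr1\t200\t100", "chr1\tx\t100", "chr1\t100"])
    def test_malformed_line_names_line_number(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\n" + line + "\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(p)

    def test_round_trip_preserves_coordinates(self, tmp_path, rng):
        original = random_interval_set(rng, 100)
        path = tmp_path / "rt.bed"
        write_bed(original, path)
        recovered = read_bed(path)
        assert [(i.chrom, i.start, i.end) for i in recovered] == [
            (i.chrom, i.start, i.end) for i in original
        ]

    def test_gzip_round_trip(self, tmp_path, rng):
        original = random_interval_set(rng, 20)
        path = tmp_path / "rt.bed.gz"
        write_bed(original, path)
        assert read_bed(path) == original

    def test_empty_set_writes_no_data_lines(self, tmp_path):
        path = tmp_path / "e.bed"
        write_bed(IntervalSet(), path)
        assert path.read_text() == ""


class TestOverlaps:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("chr1", 100, 200), ("chr1", 150, 250), True),
            (("chr1", 0, 10), ("chr1", 10, 20), False),  # half-open adjacency
            (("chr1", 100, 200), ("chr2", 100, 200), False),
        ],
    )
    def test_examples(self, a, b, expected):
        assert overlaps(iv(*a), iv(*b)) is expected

    def test_min_bp_threshold(self):
        a, b = iv("chr1", 0, 100), iv("chr1", 90, 200)
        assert overlaps(a, b, min_bp=10)
        assert not overlaps(a, b, min_bp=11)

    def test_symmetry_and_oracle_agreement(self, rng):
        s1 = random_interval_set(rng, 60)
        s2 = random_interval_set(rng, 60)
        for a in s1:
            for b in s2:
                for k in (1, 50):
                    assert overlaps(a, b, k) == overlaps(b, a, k)
                    assert overlaps(a, b, k) == brute_force_overlaps(a, b, k)

    def test_tree_query_matches_all_pairs_oracle(self, rng):
        queries = random_interval_set(rng, 200)
        subjects = random_interval_set(rng, 200)
        for q in queries:
            tree_hits = set(subjects.overlapping(q))
            brute_hits = {s for s in subjects if brute_force_overlaps(q, s)}
            assert tree_hits == brute_hits


class TestFilters:
    def test_subtract_control_removes_whole_overlapping_peaks(self):
        peaks = IntervalSet([iv("chr1", 100, 200), iv("chr1", 300, 400)])
        control = IntervalSet([iv("chr1", 150, 160)])
        assert list(subtract_control(peaks, control)) == [iv("chr1", 300, 400)]

    def test_subtract_empty_control_is_identity(self, rng):
        peaks = random_interval_set(rng, 30)
        assert subtract_control(peaks, IntervalSet()) == peaks

    def test_subtract_everything_gives_empty(self, rng):
        peaks = random_interval_set(rng, 30)
        assert subtract_control(peaks, peaks).size() == 0

    def test_peak_conservation(self, rng):
        """Kept + removed partitions the input: nothing is clipped or lost."""
        peaks = random_interval_set(rng, 80)
        control = random_interval_set(rng, 40)
        kept = set(subtract_control(peaks, control))
        removed = {p for p in peaks if control.any_overlap(p)}
        assert kept | removed == set(peaks)
        assert not (kept & removed)

    def test_blacklist_disjoint_reports_zero_removed(self):
        peaks = IntervalSet([iv("chr1", 0, 100)])
        filtered, removed = blacklist_filter(peaks, IntervalSet([iv("chr2", 0, 100)]))
        assert filtered == peaks and removed == 0

    def test_blacklist_hit_counted(self):
        peaks = IntervalSet([iv("chr1", 50, 60)])
        filtered, removed = blacklist_filter(peaks, IntervalSet([iv("chr1", 0, 100)]))
        assert filtered.size() == 0 and removed == 1

    def test_empty_blacklist_is_identity(self, rng):
        peaks = random_interval_set(rng, 30)
        filtered, removed = blacklist_filter(peaks, IntervalSet())
        assert filtered == peaks and removed == 0

    def test_replicate_intersection_keeps_rep1_frame(self):
        rep1 = IntervalSet([iv("chr1", 100, 200), iv("chr1", 500, 600)])
        rep2 = IntervalSet([iv("chr1", 150, 250)])
        assert list(replicate_intersection(rep1, rep2)) == [iv("chr1", 100, 200)]

    def test_replicate_intersection_identity_and_disjoint(self, rng):
        reps = random_interval_set(rng, 40)
        assert replicate_intersection(reps, reps) == reps
        far = IntervalSet([iv("chrX", 0, 10)])
        assert replicate_intersection(reps, far).size() == 0

    def test_multi_hit_peak_counted_once(self):
        rep1 = IntervalSet([iv("chr1", 0, 1000)])
        rep2 = IntervalSet([iv("chr1", 10, 20), iv("chr1", 500, 600)])
        assert replicate_intersection(rep1, rep2).size() == 1

    def test_merged_convention_clips_to_intersections(self):
        rep1 = IntervalSet([iv("chr1", 0, 300)])
        rep2 = IntervalSet([iv("chr1", 100, 400)])
        (merged,) = replicate_intersection(rep1, rep2, report="merged")
        assert (merged.start, merged.end) == (100, 300)


class TestSpecificityPipeline:
    def test_recovers_planted_regions_from_synthetic_replicates(self):
        chrom_sizes = {"chr1": 2_000_000, "chr2": 2_000_000}
        target = GenomicInterval("chr1", 1_000_000, 1_000_600)
        rep1, rep2, control, truth = simulate_capture_peaks(
            chrom_sizes, target, n_interactions=5, n_shared_background=20,
            reproducibility=1.0, jitter_bp=0, seed=1,
        )
        result = specificity_pipeline([rep1, rep2], [control])
        got = {(i.chrom, i.start, i.end) for i in result}
        expected = {tuple(r[:3]) for r in truth["planted_regions"]}
        assert got == expected
        assert len(result) == 6

    def test_single_rep_no_controls_is_identity(self, rng):
        rep = random_interval_set(rng, 25)
        assert specificity_pipeline([rep]) == rep

    def test_controls_identical_to_targets_empty_output(self, rng):
        rep = random_interval_set(rng, 25)
        assert specificity_pipeline([rep, rep], [rep]).size() == 0

    def test_empty_target_list_is_usage_error(self):
        with pytest.raises(ValueError):
            specificity_pipeline([])

    def test_output_monotone_in_controls_and_replicates(self, rng):
        reps = [random_interval_set(rng, 60) for _ in range(3)]
        controls = [random_interval_set(rng, 20) for _ in range(2)]
        base = specificity_pipeline(reps[:2], [controls[0]]).size()
        more_control = specificity_pipeline(reps[:2], controls).size()
        more_reps = specificity_pipeline(reps, [controls[0]]).size()
        assert more_control <= base
        assert more_reps <= base


class TestTn5Offset:
    def test_plus_strand_shifts_forward_4(self):
        out = tn5_offset(iv("chr1", 100, 150, strand="+"))
        assert (out.start, out.end) == (104, 154)

    def test_minus_strand_shifts_back_5(self):
        out = tn5_offset(iv("chr1", 100, 150, strand="-"))
        assert (out.start, out.end) == (95, 145)

    def test_clamped_at_origin_preserves_length(self):
        out = tn5_offset(iv("chr1", 2, 50, strand="-"))
        assert (out.start, out.end) == (0, 48)
        assert len(out) == 48

    def test_unstranded_read_rejected(self):
        with pytest.raises(ValueError):
            tn5_offset(iv("chr1", 100, 150))


@settings(max_examples=50, derandomize=True)
@given(
    start_a=st.integers(0, 1000), len_a=st.integers(1, 200),
    start_b=st.integers(0, 1000), len_b=st.integers(1, 200),
    min_bp=st.integers(1, 50),
)
def test_overlap_symmetry_property(start_a, len_a, start_b, len_b, min_bp):
    a = GenomicInterval("chr1", start_a, start_a + len_a)
    b = GenomicInterval("chr1", start_b, start_b + len_b)
    assert overlaps(a, b, min_bp) == overlaps(b, a, min_bp)
    assert overlaps(a, b, min_bp) == brute_force_overlaps(a, b, min_bp)
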