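"""TSS distances, relative-position classes, batch annotation vs brute force."""

import numpy as np
import pytest

from conftest import random_region_set
from oracles import brute_nearest, brute_overlapping
from peakannot import (
    GenomicRegion, RegionSet, ValidationError, annotate_peaks,
    classify_relative_position, distance_histogram, feature_tss,
    relative_position_counts, signed_distance,
)
from peakannot.annotate import NEAREST, OVERLAPPING, INSIDE_FEATURE_CLASSES


def region(chrom, start, end, name="r", strand="*"):
    return GenomicRegion(chrom, start, end, name, strand)


class TestTssAndDistance:
    def test_tss_is_start_on_forward_end_on_reverse(self):
        assert feature_tss(region("chr1", 967659, 967869, "t1", "+")) == 967659
        assert feature_tss(region("chr3", 2496700, 2496920, "t3", "-")) == 2496920

    def test_width_one_feature_tss_is_its_only_base(self):
        for strand in "+-":
            assert feature_tss(region("c", 42, 42, "f", strand)) == 42

    def test_unstranded_feature_rejected(self):
        with pytest.raises(ValidationError, match="strand"):
            feature_tss(region("c", 1, 5, "f", "*"))
        with pytest.raises(ValidationError, match="strand"):
            signed_distance(region("c", 1, 5, "p"), region("c", 1, 5, "f", "*"))

    def test_signed_distance_worked_examples(self):
        # forward strand: peak start 5 bases 5' of the TSS
        assert signed_distance(region("1", 967654, 967754, "Site1"),
                               region("1", 967659, 967869, "t1", "+")) == -5
        # reverse strand: TSS at the feature end, peak start inside the body
        assert signed_distance(region("3", 2496704, 2496804, "Site3"),
                               region("3", 2496700, 2496920, "t3", "-")) == 216

    @pytest.mark.parametrize("strand", "+-")
    def test_distance_zero_when_peak_start_at_tss(self, strand):
        tss = 500
        feat = region("c", 500, 800, "f", "+") if strand == "+" else \
            region("c", 200, 500, "f", "-")
        assert signed_distance(region("c", tss, tss + 50, "p"), feat) == 0


class TestClassify:
    @pytest.mark.parametrize("peak,feat,expected", [
        # covers the 5' boundary only
        ((967654, 967754), ("+", 967659, 967869), "overlapStart"),
        # strictly inside a reverse-strand feature
        ((2496704, 2496804), ("-", 2496700, 2496920), "inside"),
        # full containment of the feature
        ((1, 1000), ("+", 400, 600), "includeFeature"),
        # left of a reverse-strand feature is past its 3' end -> downstream
        ((100, 200), ("-", 300, 400), "downstream"),
        ((100, 200), ("+", 300, 400), "upstream"),
        # covers the 3' boundary only (forward strand end)
        ((550, 700), ("+", 400, 600), "overlapEnd"),
    ])
    def test_worked_geometries(self, peak, feat, expected):
        strand, fs, fe = feat
        assert classify_relative_position(
            region("c", *peak, "p"), region("c", fs, fe, "f", strand)
        ) == expected

    def test_exhaustive_exclusive_over_small_grid(self):
        """Exactly one class for every peak/feature pair on [1,10], both strands."""
        intervals = [(s, e) for s in range(1, 11) for e in range(s, 11)]
        for ps, pe in intervals:
            peak = region("c", ps, pe, "p")
            for fs, fe in intervals:
                for strand in "+-":
                    feat = region("c", fs, fe, "f", strand)
                    cls = classify_relative_position(peak, feat)
                    assert cls in INSIDE_FEATURE_CLASSES
                    intersects = ps <= fe and fs <= pe
                    if cls in ("upstream", "downstream"):
                        assert not intersects
                    elif cls == "includeFeature":
                        assert ps <= fs and fe <= pe
                    else:
                        assert intersects

    def test_mirror_symmetry(self):
        """Reflecting coordinates and flipping strands preserves every class,
        and preserves signed distances for width-1 peaks (whose start is
        their end, the reflection's anchor)."""
        rng = np.random.default_rng(7)
        C = 3000
        for _ in range(300):
            ps = int(rng.integers(1, 1200))
            pw = int(rng.integers(1, 80))
            fs = int(rng.integers(1, 1200))
            fw = int(rng.integers(1, 200))
            strand = "+-"[int(rng.integers(0, 2))]
            peak = region("c", ps, ps + pw - 1, "p")
            feat = region("c", fs, fs + fw - 1, "f", strand)
            m_peak = region("c", C - peak.end, C - peak.start, "p")
            m_feat = region("c", C - feat.end, C - feat.start, "f",
                            "-" if strand == "+" else "+")
            assert classify_relative_position(peak, feat) == \
                classify_relative_position(m_peak, m_feat)
            if pw == 1:
                assert signed_distance(peak, feat) == signed_distance(m_peak, m_feat)


class TestAnnotatePeaks:
    def test_overlapping_mode_on_worked_example(self, myexp, literature):
        rows = annotate_peaks(myexp, literature, output="overlapping",
                              maxgap=0, multiple=False)
        assert [(r.peak.name, r.feature.name, r.distance_to_feature) for r in rows] \
            == [("Site1", "t1", -5), ("Site2", "t2", -1), ("Site3", "t3", 216)]
        assert all(r.from_overlapping_or_nearest == OVERLAPPING for r in rows)

    def test_nearest_mode_prefers_smaller_absolute_distance(self, myexp, literature):
        rows = annotate_peaks(myexp, literature, output="nearest")
        by_peak = {r.peak.name: r for r in rows}
        # t4's TSS (3076166) is ~2.1 Mb away; t1 wins at |d| = 5
        assert by_peak["Site1"].feature.name == "t1"
        assert by_peak["Site1"].distance_to_feature == -5

    def test_both_mode_collapses_nearest_equal_overlap(self):
        peaks = RegionSet("p", [region("c", 400, 600, "p1")])
        feats = RegionSet("f", [region("c", 400, 600, "f1", "+")])
        rows = annotate_peaks(peaks, feats, output="both")
        assert len(rows) == 1
        r = rows[0]
        assert (r.from_overlapping_or_nearest, r.distance_to_feature,
                r.inside_feature) == (NEAREST, 0, "includeFeature")

    def test_both_mode_adds_nonnearest_overlaps(self):
        peaks = RegionSet("p", [region("c", 500, 509, "p1")])
        feats = RegionSet("f", [
            region("c", 505, 900, "near", "+"),    # TSS 505, |d| = 5
            region("c", 100, 600, "wrap", "+"),    # overlapping, TSS 100
        ])
        rows = annotate_peaks(peaks, feats, output="both", multiple=True)
        tags = {(r.feature.name, r.from_overlapping_or_nearest) for r in rows}
        assert tags == {("near", NEAREST), ("wrap", OVERLAPPING)}

    def test_peak_on_absent_chromosome_yields_empty_row(self):
        peaks = RegionSet("p", [region("chrZ", 5, 10, "lost")])
        feats = RegionSet("f", [region("chrA", 1, 100, "f1", "+")])
        rows = annotate_peaks(peaks, feats, output="nearest")
        assert rows[0].feature is None and rows[0].distance_to_feature is None

    def test_no_overlap_yields_empty_row_in_overlapping_mode(self):
        peaks = RegionSet("p", [region("chrA", 500, 510, "p1")])
        feats = RegionSet("f", [region("chrA", 1, 100, "f1", "+")])
        rows = annotate_peaks(peaks, feats, output="overlapping", maxgap=0)
        assert len(rows) == 1 and rows[0].feature is None

    @pytest.mark.parametrize("bad_kwargs,fragment", [
        (dict(output="closest"), "output"),
        (dict(maxgap=-1), "maxgap"),
    ])
    def test_bad_arguments(self, myexp, literature, bad_kwargs, fragment):
        with pytest.raises(ValidationError, match=fragment):
            annotate_peaks(myexp, literature, **bad_kwargs)

    def test_empty_feature_set_rejected(self, myexp):
        with pytest.raises(ValidationError, match="empty"):
            annotate_peaks(myexp, RegionSet("f"))

    def test_unstranded_features_rejected_with_names(self, myexp):
        feats = RegionSet("f", [region("1", 1, 10, "u1", "*")])
        with pytest.raises(ValidationError, match="u1"):
            annotate_peaks(myexp, feats)

    def test_matches_brute_force_on_random_instances(self):
        """Nearest and overlapping modes vs the O(n*m) oracle."""
        rng = np.random.default_rng(11)
        for trial in range(60):
            peaks = random_region_set(rng, "p", int(rng.integers(1, 31)))
            feats = random_region_set(rng, "f", int(rng.integers(1, 31)),
                                      stranded=True)
            maxgap = int(rng.integers(0, 30))
            near_rows = annotate_peaks(peaks, feats, output="nearest")
            for row in near_rows:
                expected = brute_nearest(row.peak, feats)
                if expected is None:
                    assert row.feature is None
                else:
                    assert row.feature.name == expected[0].name
                    assert row.distance_to_feature == expected[1]
            ovl_rows = annotate_peaks(peaks, feats, output="overlapping",
                                      maxgap=maxgap, multiple=True)
            got = {(r.peak.name, r.feature.name)
                   for r in ovl_rows if r.feature is not None}
            want = {(p.name, f.name)
                    for p in peaks for f in brute_overlapping(p, feats, maxgap)}
            assert got == want


class TestPlantedOffsets:
    @pytest.mark.parametrize("d", [0, 1, 50, 500])
    def test_planted_offset_recovered_exactly(self, d):
        from peakannot import FixtureSpec, make_gene_models, make_peaks

        spec = FixtureSpec(seed=13, n_genes=20, min_gene_gap=2500,
                           placement="planted_offset",
                           planted_offset_distance=d, n_peaks=40)
        genes = make_gene_models(spec)
        peaks = make_peaks(spec, genes=genes)
        rows = annotate_peaks(peaks, genes, output="nearest")
        assert [r.distance_to_feature for r in rows] == [-d] * len(peaks)


class TestSummaries:
    def test_distance_histogram_half_open_bins(self):
        rows = [
            GenomicRegion("c", 1, 1, "dummy"),  # placeholder, replaced below
        ]
        # build minimal annotated rows directly
        from peakannot import AnnotatedPeak
        feat = region("c", 100, 200, "f", "+")
        rows = [
            AnnotatedPeak(region("c", 95, 96, "a"), feat, -5, "upstream", NEAREST),
            AnnotatedPeak(region("c", 316, 317, "b"), feat, 216, "downstream", NEAREST),
        ]
        h = distance_histogram(rows, (-100, 0, 100, 300))
        assert h.counts == (1, 0, 1)
        assert h.underflow == h.overflow == 0
        assert h.total == 2

    def test_histogram_interior_edge_goes_to_right_bin(self):
        from peakannot import AnnotatedPeak
        feat = region("c", 100, 200, "f", "+")
        rows = [AnnotatedPeak(region("c", 100, 101, "a"), feat, 0, "overlapStart", NEAREST)]
        h = distance_histogram(rows, (-100, 0, 100))
        assert h.counts == (0, 1)

    def test_histogram_overflow_and_filtering(self):
        from peakannot import AnnotatedPeak
        feat = region("c", 100, 200, "f", "+")
        rows = [
            AnnotatedPeak(region("c", 5000, 5001, "a"), feat, 4900, "downstream", NEAREST),
            AnnotatedPeak(region("c", 150, 151, "b"), feat, 50, "inside", OVERLAPPING),
            AnnotatedPeak(region("c", 1, 2, "c"), None, None, None, NEAREST),
        ]
        h = distance_histogram(rows, (0, 100))
        assert h.counts == (0,) and h.overflow == 1 and h.underflow == 0

    def test_histogram_empty_rows_all_zero(self):
        h = distance_histogram([], (0, 10, 20))
        assert h.counts == (0, 0) and h.total == 0

    def test_histogram_rejects_unsorted_breaks(self):
        with pytest.raises(ValidationError, match="increasing"):
            distance_histogram([], (10, 0))

    def test_relative_position_counts_precedence(self):
        from peakannot import AnnotatedPeak
        feat = region("c", 100, 200, "f", "+")
        pa, pb = region("c", 150, 160, "A"), region("c", 10, 20, "B")
        rows = [
            AnnotatedPeak(pa, feat, 50, "inside", OVERLAPPING),
            AnnotatedPeak(pa, feat, 50, "upstream", NEAREST),
            AnnotatedPeak(pb, feat, -90, "upstream", NEAREST),
        ]
        assert relative_position_counts(rows) == {"inside": 1, "upstream": 1}

    def test_relative_position_counts_plain_tally_without_overlaps(self):
        from peakannot import AnnotatedPeak
        feat = region("c", 100, 200, "f", "+")
        rows = [
            AnnotatedPeak(region("c", 10, 20, "A"), feat, -90, "upstream", NEAREST),
            AnnotatedPeak(region("c", 30, 40, "B"), feat, -70, "upstream", NEAREST),
        ]
        assert relative_position_counts(rows) == {"upstream": 2}

    def test_relative_position_counts_multiple_overlaps_all_kept(self):
        from peakannot import AnnotatedPeak
        f1 = region("c", 100, 200, "f1", "+")
        f2 = region("c", 140, 300, "f2", "+")
        p = region("c", 150, 160, "A")
        rows = [
            AnnotatedPeak(p, f1, 50, "inside", OVERLAPPING),
            AnnotatedPeak(p, f2, 10, "overlapStart", OVERLAPPING),
        ]
        assert relative_position_counts(rows) == {"inside": 1, "overlapStart": 1}
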