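"""Region extraction, summary statistics, and feature-matrix assembly."""

import numpy as np
import pytest

from svds.features import (
    FeatureCatalog,
    FeatureSpec,
    annotate_set,
    build_default_catalog,
    extract_regions,
    summarize,
    summarize_pooled,
)
from svds.intervals import (
    AnnotationTrack,
    DataError,
    ElementCatalog,
    GenomicInterval,
    SVRecord,
)


class TestExtractRegions:
    def test_deletion_span_and_flanks(self):
        sv = SVRecord(GenomicInterval("chr1", 1000, 2000), "DEL", "d")
        span, (up, down) = extract_regions(sv, flank_size=100)
        assert span == GenomicInterval("chr1", 1000, 2000)
        assert up == GenomicInterval("chr1", 900, 1000)
        assert down == GenomicInterval("chr1", 2000, 2100)

    def test_insertion_point_site(self):
        sv = SVRecord(GenomicInterval("chr1", 500, 501), "INS", "i")
        span, (up, down) = extract_regions(sv, flank_size=100)
        assert span == GenomicInterval("chr1", 500, 501)
        assert up == GenomicInterval("chr1", 400, 500)
        assert down == GenomicInterval("chr1", 501, 601)

    def test_clipping_at_chromosome_bounds(self):
        sv = SVRecord(GenomicInterval("chr1", 20, 120), "DEL", "d")
        span, (up, down) = extract_regions(sv, 100, chrom_sizes={"chr1": 150})
        assert up == GenomicInterval("chr1", 0, 20)
        assert down == GenomicInterval("chr1", 120, 150)


class TestSummarize:
    def test_full_coverage(self):
        track = AnnotationTrack("t", [("chr1", 0, 100, 2.0)])
        region = GenomicInterval("chr1", 0, 100)
        assert summarize(track, region, "mean") == 2.0
        assert summarize(track, region, "sum") == 200.0
        assert summarize(track, region, "max") == 2.0

    def test_half_coverage_uncovered_counts_as_zero(self):
        track = AnnotationTrack("t", [("chr1", 0, 50, 4.0)])
        region = GenomicInterval("chr1", 0, 100)
        # per-base oracle: 50 bases of 4.0, 50 of 0 -> mean 2.0, sum 200
        assert summarize(track, region, "mean") == 2.0
        assert summarize(track, region, "sum") == 200.0
        assert summarize(track, region, "max") == 4.0

    def test_count_above_p90_counts_bases(self):
        # 900 bases at 1.0, 100 bases at 9.0 -> p90 interpolates just below 9
        rows = [("chr1", 0, 900, 1.0), ("chr1", 900, 1000, 9.0)]
        track = AnnotationTrack("t", rows)
        region = GenomicInterval("chr1", 870, 970)
        per_base = np.array([1.0] * 30 + [9.0] * 70)
        oracle = int((per_base >= track.p90_threshold).sum())
        assert summarize(track, region, "count_above_p90") == oracle == 70

    def test_no_overlap_imputes_zero(self):
        track = AnnotationTrack("t", [("chr1", 0, 10, 5.0)])
        region = GenomicInterval("chr2", 0, 100)
        for stat in ("max", "mean", "sum", "count_above_p90"):
            assert summarize(track, region, stat) == 0.0

    def test_pooled_flanks(self):
        track = AnnotationTrack("t", [("chr1", 0, 100, 2.0), ("chr1", 200, 300, 6.0)])
        regions = [GenomicInterval("chr1", 50, 100), GenomicInterval("chr1", 200, 250)]
        assert summarize_pooled(track, regions, "max") == 6.0
        assert summarize_pooled(track, regions, "sum") == 50 * 2.0 + 50 * 6.0
        assert summarize_pooled(track, regions, "mean") == pytest.approx(4.0)


@pytest.fixture
def toy_setup():
    tracks = {
        "cons": AnnotationTrack(
            "cons", [("chr1", 0, 500, 1.0), ("chr1", 500, 600, 8.0)]
        ),
        "chip": AnnotationTrack("chip", [("chr1", 300, 400, 3.0)]),
    }
    catalogs = {
        "gene": ElementCatalog("gene", [("chr1", 450, 700)]),
        "exon": ElementCatalog("exon", [("chr1", 470, 520)]),
    }
    catalog = build_default_catalog(tracks, catalogs, flank_size=100)
    return tracks, catalogs, catalog


class TestAnnotateSet:
    def test_sv_overlapping_nothing_is_all_zero_except_distance(self, toy_setup):
        tracks, catalogs, catalog = toy_setup
        sv = SVRecord(GenomicInterval("chr9", 100, 200), "DEL", "nowhere")
        span_m, flank_m = annotate_set([sv], catalog, tracks, catalogs)
        for m in (span_m, flank_m):
            for name, tag in m.region_tags.items():
                value = m.df.loc["nowhere", name]
                if tag == "distance":
                    assert value == 10_000_000  # no-element sentinel
                else:
                    assert value == 0.0

    def test_identical_svs_identical_rows(self, toy_setup):
        tracks, catalogs, catalog = toy_setup
        svs = [
            SVRecord(GenomicInterval("chr1", 100, 400), "DEL", "a"),
            SVRecord(GenomicInterval("chr1", 100, 400), "DEL", "b"),
        ]
        span_m, flank_m = annotate_set(svs, catalog, tracks, catalogs)
        assert span_m.df.loc["a"].equals(span_m.df.loc["b"])
        assert flank_m.df.loc["a"].equals(flank_m.df.loc["b"])

    def test_row_equals_composition_of_individual_calls(self, toy_setup):
        tracks, catalogs, catalog = toy_setup
        sv = SVRecord(GenomicInterval("chr1", 250, 550), "DEL", "x")
        span, flanks = extract_regions(sv, catalog.flank_size)
        span_m, flank_m = annotate_set([sv], catalog, tracks, catalogs)
        for entry in catalog.entries:
            if entry.statistic == "nearest_distance":
                want = catalogs[entry.source].nearest_distance(span)
                assert span_m.df.loc["x", entry.name] == want
                assert flank_m.df.loc["x", entry.name] == want
            elif entry.statistic == "overlap_count":
                if entry.region_kind == "span":
                    want = catalogs[entry.source].overlap_count(span)
                    assert span_m.df.loc["x", entry.name] == want
                else:
                    want = sum(catalogs[entry.source].overlap_count(f) for f in flanks)
                    assert flank_m.df.loc["x", entry.name] == want
            elif entry.region_kind == "span":
                want = summarize(tracks[entry.source], span, entry.statistic)
                assert span_m.df.loc["x", entry.name] == pytest.approx(want)
            else:
                want = summarize_pooled(tracks[entry.source], flanks, entry.statistic)
                assert flank_m.df.loc["x", entry.name] == pytest.approx(want)

    def test_unknown_source_fails_before_computation(self, toy_setup):
        tracks, catalogs, _ = toy_setup
        bad = FeatureCatalog([FeatureSpec("ghost.max.span", "ghost", "span", "max")])
        with pytest.raises(DataError, match="ghost"):
            annotate_set([], bad, tracks, catalogs)

    def test_matrix_is_finite(self, toy_setup):
        tracks, catalogs, catalog = toy_setup
        rng = np.random.default_rng(0)
        svs = [
            SVRecord(GenomicInterval("chr1", int(s), int(s) + 50), "DEL", f"r{i}")
            for i, s in enumerate(rng.integers(0, 900, size=30))
        ]
        span_m, flank_m = annotate_set(svs, catalog, tracks, catalogs)
        assert np.isfinite(span_m.df.to_numpy()).all()
        assert np.isfinite(flank_m.df.to_numpy()).all()


@pytest.mark.parametrize("seed", range(3))
def test_sum_and_count_monotone_under_span_extension(seed):
    rng = np.random.default_rng(seed)
    rows = []
    pos = 0
    for _ in range(20):
        width = int(rng.integers(10, 100))
        rows.append(("chr1", pos, pos + width, float(rng.exponential(1.0))))
        pos += width + int(rng.integers(0, 50))
    track = AnnotationTrack("t", rows)
    start = int(rng.integers(0, 200))
    prev_sum = prev_count = -1.0
    for end in range(start + 10, pos, 137):
        region = GenomicInterval("chr1", start, end)
        s = summarize(track, region, "sum")
        c = summarize(track, region, "count_above_p90")
        assert s >= prev_sum and c >= prev_count
        prev_sum, prev_count = s, c


def test_translation_invariance():
    offset = 12_345
    rows = [("chr1", 100, 200, 2.5), ("chr1", 250, 400, 1.5)]
    tracks_a = {"t": AnnotationTrack("t", rows)}
    tracks_b = {
        "t": AnnotationTrack("t", [(c, s + offset, e + offset, v) for c, s, e, v in rows])
    }
    cats_a = {"e": ElementCatalog("e", [("chr1", 300, 350)])}
    cats_b = {"e": ElementCatalog("e", [("chr1", 300 + offset, 350 + offset)])}
    sv_a = SVRecord(GenomicInterval("chr1", 150, 320), "DEL", "x")
    sv_b = SVRecord(GenomicInterval("chr1", 150 + offset, 320 + offset), "DEL", "x")
    catalog = build_default_catalog(tracks_a, cats_a)
    span_a, flank_a = annotate_set([sv_a], catalog, tracks_a, cats_a)
    span_b, flank_b = annotate_set([sv_b], catalog, tracks_b, cats_b)
    assert span_a.df.equals(span_b.df)
    assert flank_a.df.equals(flank_b.df)


def test_duplicate_feature_names_rejected():
    e = FeatureSpec("dup", "t", "span", "max")
    with pytest.raises(DataError):
        FeatureCatalog([e, e])


def test_catalog_yaml_round_trip(tmp_path):
    catalog = FeatureCatalog(
        [
            FeatureSpec("cons.max.span", "cons", "span", "max"),
            FeatureSpec("gene.dist", "gene", "span", "nearest_distance"),
        ],
        flank_size=250,
    )
    p = tmp_path / "catalog.yaml"
    catalog.to_yaml(p)
    back = FeatureCatalog.from_yaml(p)
    assert back.entries == catalog.entries and back.flank_size == 250
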