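"""Interval primitives, BED-like parsing, and overlap/distance queries."""

import numpy as np
import pytest

from svds.intervals import (
    NO_ELEMENT_DISTANCE,
    AnnotationTrack,
    DataError,
    ElementCatalog,
    GenomicInterval,
    SVRecord,
    length_weighted_percentile,
    nearest_distance,
    overlap_values,
    read_catalog,
    read_sv_table,
    read_track,
    write_catalog,
    write_sv_table,
    write_track,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestSVTable:
    def test_basic_parse(self, tmp_path):
        p = _write(tmp_path, "svs.tsv", "chr1\t100\t600\tsv1\tDEL\n")
        (rec,) = read_sv_table(p)
        assert rec.interval == GenomicInterval("chr1", 100, 600)
        assert rec.sv_type == "DEL" and rec.interval.length == 500

    def test_point_insertion_normalised(self, tmp_path):
        p = _write(tmp_path, "svs.tsv", "chr1\t100\t100\tsv2\tINS\n")
        (rec,) = read_sv_table(p)
        assert (rec.interval.start, rec.interval.end) == (100, 101)

    def test_reversed_coordinates_cite_line(self, tmp_path):
        p = _write(tmp_path, "svs.tsv", "chr1\t600\t100\tx\tDEL\n")
        with pytest.raises(DataError, match=r":1:"):
            read_sv_table(p)

    def test_unknown_type_cites_line(self, tmp_path):
        p = _write(
            tmp_path, "svs.tsv", "chr1\t1\t10\ta\tDEL\nchr1\t5\t50\tb\tINV\n"
        )
        with pytest.raises(DataError, match=r":2:.*INV"):
            read_sv_table(p)

    def test_header_detected_and_allele_columns(self, tmp_path):
        p = _write(
            tmp_path,
            "svs.tsv",
            "chrom\tstart\tend\tname\ttype\tac\taf\n"
            "chr2\t10\t400\tsv9\tDUP\t1\t0.0005\n",
        )
        (rec,) = read_sv_table(p)
        assert rec.is_singleton and rec.allele_frequency == 0.0005

    def test_round_trip(self, tmp_path):
        records = [
            SVRecord(GenomicInterval("chr1", 0, 100), "DEL", "a", 3, 0.0015),
            SVRecord(GenomicInterval("chr2", 7, 8), "INS", "b"),
            SVRecord(GenomicInterval("chr2", 50, 220), "DUP", "c", 1, None),
        ]
        p = tmp_path / "out.tsv"
        write_sv_table(records, p)
        assert read_sv_table(p) == records


class TestTrack:
    def test_constant_track_p90(self, tmp_path):
        p = _write(tmp_path, "t.bed", "chr1\t0\t1000\t5.0\n")
        track = read_track(p, "t")
        assert track.p90_threshold == 5.0

    def test_ten_interval_p90_linear_interpolation(self, tmp_path):
        lines = "".join(
            f"chr1\t{i * 100}\t{(i + 1) * 100}\t{i + 1}.0\n" for i in range(10)
        )
        track = read_track(_write(tmp_path, "t.bed", lines), "t")
        # brute-force per-base oracle: expand to 1000 per-base values
        per_base = np.repeat(np.arange(1.0, 11.0), 100)
        assert track.p90_threshold == pytest.approx(np.percentile(per_base, 90))
        assert track.p90_threshold == pytest.approx(9.1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_p90_matches_per_base_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 30)
        widths = rng.integers(1, 50, size=n)
        values = rng.normal(size=n)
        assert length_weighted_percentile(values, widths, 90.0) == pytest.approx(
            np.percentile(np.repeat(values, widths), 90)
        )

    def test_empty_track_error(self, tmp_path):
        with pytest.raises(DataError, match="empty track"):
            read_track(_write(tmp_path, "t.bed", ""), "t")

    def test_non_numeric_score_cites_line(self, tmp_path):
        p = _write(tmp_path, "t.bed", "chr1\t0\t10\t1.0\nchr1\t10\t20\tNA\n")
        with pytest.raises(DataError, match=r":2:"):
            read_track(p, "t")

    def test_overlap_values_clip(self):
        track = AnnotationTrack("t", [("chr1", 50, 150, 2.0)])
        assert overlap_values(GenomicInterval("chr1", 0, 100), track) == [(50, 2.0)]
        assert overlap_values(GenomicInterval("chr1", 200, 300), track) == []
        assert overlap_values(GenomicInterval("chr2", 0, 100), track) == []

    def test_overlap_values_multi_interval_coverage(self):
        track = AnnotationTrack(
            "t", [("chr1", 0, 100, 1.0), ("chr1", 100, 200, 2.0), ("chr1", 200, 300, 3.0)]
        )
        got = overlap_values(GenomicInterval("chr1", 50, 250), track)
        assert got == [(50, 1.0), (100, 2.0), (50, 3.0)]
        assert sum(c for c, _ in got) == 200

    @pytest.mark.parametrize("seed", range(5))
    def test_overlap_values_agree_with_per_base_scan(self, seed):
        rng = np.random.default_rng(seed)
        genome = 300
        rows = []
        for _ in range(rng.integers(1, 10)):
            s = int(rng.integers(0, genome - 1))
            e = int(rng.integers(s + 1, genome))
            rows.append(("chr1", s, e, float(rng.integers(1, 5))))
        track = AnnotationTrack("t", rows)
        # per-base oracle with per-base max resolution of overlaps
        base = np.zeros(genome)
        covered = np.zeros(genome, dtype=bool)
        for _, s, e, v in rows:
            base[s:e] = np.maximum(base[s:e], v)
            covered[s:e] = True
        qs = int(rng.integers(0, genome - 1))
        qe = int(rng.integers(qs + 1, genome))
        got = overlap_values(GenomicInterval("chr1", qs, qe), track)
        assert sum(c for c, _ in got) == int(covered[qs:qe].sum())
        assert sum(c * v for c, v in got) == pytest.approx(base[qs:qe].sum())
        assert sum(c for c, _ in got) <= qe - qs

    def test_overlapping_inputs_resolved_to_per_base_max(self):
        track = AnnotationTrack(
            "t", [("chr1", 0, 100, 1.0), ("chr1", 50, 150, 3.0)]
        )
        got = overlap_values(GenomicInterval("chr1", 0, 150), track)
        assert got == [(50, 1.0), (100, 3.0)]

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        rows = [
            ("chr1", int(i * 10), int(i * 10 + 10), float(v))
            for i, v in enumerate(rng.normal(size=20))
        ]
        track = AnnotationTrack("t", rows, group="conservation_constraint")
        p = tmp_path / "t.bed"
        write_track(track, p)
        back = read_track(p, "t", group="conservation_constraint")
        assert list(back.iter_intervals()) == list(track.iter_intervals())
        assert back.p90_threshold == track.p90_threshold


class TestNearestDistance:
    def test_gap_overlap_and_sentinel(self):
        cat = ElementCatalog("e", [("chr1", 300, 400)])
        assert nearest_distance(GenomicInterval("chr1", 100, 200), cat) == 100
        cat2 = ElementCatalog("e", [("chr1", 150, 400)])
        assert nearest_distance(GenomicInterval("chr1", 100, 200), cat2) == 0
        assert (
            nearest_distance(GenomicInterval("chr9", 100, 200), cat)
            == NO_ELEMENT_DISTANCE
        )

    def test_min_over_multiple_elements(self):
        cat = ElementCatalog("e", [("chr1", 0, 10), ("chr1", 500, 600)])
        # brute force: min(gap to [0,10)) = 90, gap to [500,600) = 300
        assert nearest_distance(GenomicInterval("chr1", 100, 200), cat) == 90

    def test_agrees_with_linear_scan_on_random_queries(self):
        rng = np.random.default_rng(42)
        elements = []
        for _ in range(50):
            s = int(rng.integers(0, 9_000))
            elements.append(("chr1", s, s + int(rng.integers(1, 500))))
        cat = ElementCatalog("e", elements)
        for _ in range(1000):
            qs = int(rng.integers(0, 9_500))
            qe = qs + int(rng.integers(1, 400))
            q = GenomicInterval("chr1", qs, qe)
            oracle = min(
                max(s - qe, qs - e, 0) for _, s, e in elements
            )
            assert nearest_distance(q, cat) == oracle

    def test_catalog_round_trip(self, tmp_path):
        cat = ElementCatalog("e", [("chr1", 5, 10), ("chr2", 0, 3)])
        p = tmp_path / "e.bed"
        write_catalog(cat, p)
        assert list(read_catalog(p, "e").iter_intervals()) == list(cat.iter_intervals())


def test_interval_invariants():
    with pytest.raises(DataError):
        GenomicInterval("chr1", -1, 5)
    with pytest.raises(DataError):
        GenomicInterval("chr1", 10, 5)
    assert GenomicInterval("chr1", 5, 5).length == 0
    with pytest.raises(DataError):
        SVRecord(GenomicInterval("chr1", 5, 5), "DEL", "zero-length")
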