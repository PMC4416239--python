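"""Feature overlap semantics, conservation rules and phenotype joins."""

import pandas as pd
import pytest

from rrascan.annotator import (
    FeatureTrack,
    affected_span,
    annotate_catalog,
    gerp_filter,
    join_phenotypes,
    overlap_features,
    summarize_catalog,
    write_annotation_tsv,
)
from rrascan.io_formats import BedGraphTrack, read_bed, read_tsv_table

from conftest import make_locus


def rs_track(rows):
    return BedGraphTrack(rows)


class TestAffectedSpan:
    def test_snv_is_one_base(self):
        span = affected_span(make_locus(pos=100, ref="A", alt="G"))
        assert (span.start, span.end) == (99, 100)

    def test_deletion_excludes_anchor(self):
        span = affected_span(make_locus(pos=100, ref="ATT", alt="A"))
        assert (span.start, span.end) == (100, 102)

    def test_insertion_is_a_point(self):
        span = affected_span(make_locus(pos=100, ref="A", alt="ATG"))
        assert (span.start, span.end) == (100, 100)


class TestOverlapFeatures:
    def test_snv_inside_feature(self):
        track = FeatureTrack([("chr1", 90, 110, "lincRNA")])
        assert track.overlapping_labels(make_locus(pos=100)) == {"lincRNA"}

    def test_all_three_regulatory_elements(self):
        track = FeatureTrack([("chr1", 0, 200, el) for el in ("TFP", "DHS", "enhancer")])
        assert track.overlapping_labels(make_locus(pos=100)) == {"TFP", "DHS", "enhancer"}

    def test_absent_chromosome_is_empty(self):
        track = FeatureTrack([("chr2", 0, 200, "TFP")])
        assert track.overlapping_labels(make_locus(chrom="chr1", pos=100)) == frozenset()

    def test_insertion_point_must_be_strictly_inside(self):
        locus = make_locus(pos=100, ref="A", alt="AT")  # insertion point at 0-based 100
        assert FeatureTrack([("chr1", 99, 101, "x")]).overlapping_labels(locus) == {"x"}
        # point on the interval boundary does not count
        assert FeatureTrack([("chr1", 100, 110, "x")]).overlapping_labels(locus) == frozenset()
        assert FeatureTrack([("chr1", 90, 100, "x")]).overlapping_labels(locus) == frozenset()

    def test_deletion_overlaps_via_deleted_span_only(self):
        locus = make_locus(pos=100, ref="ATT", alt="A")  # deleted span [100, 102)
        assert FeatureTrack([("chr1", 101, 150, "x")]).overlapping_labels(locus) == {"x"}
        assert FeatureTrack([("chr1", 90, 100, "x")]).overlapping_labels(locus) == frozenset()

    def test_agrees_with_quadratic_scan(self, rng):
        """Interval-tree lookup equals a brute-force scan on a random track."""
        rows = []
        for i in range(1000):
            start = int(rng.integers(0, 5000))
            rows.append(("chr1", start, start + int(rng.integers(1, 60)), f"f{i % 7}"))
        track = FeatureTrack(rows)
        loci = [make_locus(pos=int(p)) for p in rng.integers(2, 5000, size=120)]
        result = overlap_features(loci, {"t": track})
        for locus in loci:
            span = affected_span(locus)
            brute = {label for (c, s, e, label) in rows
                     if c == locus.chrom and s < span.end and e > span.start}
            assert result[locus.key]["t"] == brute

    def test_annotation_preserves_locus_set(self, catalog):
        result = overlap_features(catalog, {"t": FeatureTrack([])})
        assert set(result) == {l.key for l in catalog}


class TestGerpFilter:
    def test_strictly_greater_than_two(self):
        locus = make_locus(pos=100, ref="A", alt="G")
        assert gerp_filter(locus, rs_track([("chr1", 99, 100, 2.5)])) is True
        assert gerp_filter(locus, rs_track([("chr1", 99, 100, 2.0)])) is False

    def test_deletion_any_base_rule(self):
        locus = make_locus(pos=100, ref="ATTG", alt="A")  # deleted bases at 100..102
        scores = [("chr1", 100, 101, 1.0), ("chr1", 101, 102, 2.3), ("chr1", 102, 103, 0.1)]
        assert gerp_filter(locus, rs_track(scores)) is True
        low = [("chr1", 100, 103, 1.9)]
        assert gerp_filter(locus, rs_track(low)) is False

    def test_deletion_ignores_anchor_base_score(self):
        locus = make_locus(pos=100, ref="AT", alt="A")
        # high score on the anchor (99) must not count; deleted base (100) low
        scores = [("chr1", 99, 100, 5.0), ("chr1", 100, 101, 1.0)]
        assert gerp_filter(locus, rs_track(scores)) is False

    def test_absent_position_fails_with_warning(self, caplog):
        locus = make_locus(pos=100)
        with caplog.at_level("WARNING"):
            assert gerp_filter(locus, rs_track([])) is False
        assert "absent" in caplog.text

    def test_insertion_uses_anchor_base(self):
        locus = make_locus(pos=100, ref="A", alt="ATT")
        assert gerp_filter(locus, rs_track([("chr1", 99, 100, 3.1)])) is True


class TestJoinPhenotypes:
    def gene_model(self):
        return FeatureTrack([("chr1", 50, 150, "protein_coding", "G1"),
                             ("chr1", 140, 300, "lincRNA", "G2")])

    def gad(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "disease_class", "association"])

    def test_positive_associations_attached(self):
        gad = self.gad([("G1", "CANCER", "Y"), ("G1", "IMMUNE", "Y"), ("G1", "VISION", "N")])
        classes, omim, score = join_phenotypes(
            make_locus(pos=100), self.gene_model(), gad, {"G9"}, {})
        assert classes == {"CANCER", "IMMUNE"}  # the N record is ignored
        assert omim is False and score is None

    def test_regulomedb_score_three_is_functional(self):
        from rrascan.annotator import AnnotationRecord

        rec3 = AnnotationRecord(locus=make_locus(), regulomedb_score=3)
        rec4 = AnnotationRecord(locus=make_locus(), regulomedb_score=4)
        assert rec3.regulomedb_functional is True   # <= 3 is inclusive
        assert rec4.regulomedb_functional is False

    def test_intergenic_locus_is_empty(self):
        classes, omim, score = join_phenotypes(
            make_locus(pos=1000), self.gene_model(), self.gad([]), {"G1"}, {})
        assert classes == frozenset() and omim is False

    def test_omim_flag_from_overlapped_gene(self):
        classes, omim, _ = join_phenotypes(
            make_locus(pos=145), self.gene_model(), self.gad([]), {"G2"}, {})
        assert omim is True


class TestAnnotateCatalog:
    def test_round_trips_planted_track_truth(self, study, catalog):
        gencode = FeatureTrack(read_bed(study["gencode"]))
        encode = FeatureTrack(read_bed(study["encode"]))
        gene_model = FeatureTrack.from_bed(read_bed(study["gencode"]), 3, 4)
        rs = BedGraphTrack.load(study["gerp"])
        gad = read_tsv_table(study["gad"], ["gene_id", "disease_class", "association"])
        omim = set(read_tsv_table(study["omim"], ["gene_id"])["gene_id"])
        regdb = {(str(r.chrom), int(r.pos)): int(r.score) for r in
                 read_tsv_table(study["regulomedb"], ["chrom", "pos", "score"]
                                ).itertuples(index=False)}
        csq = {(str(r.chrom), int(r.pos), r.ref, r.alt): r.consequence for r in
               read_tsv_table(study["consequence"],
                              ["chrom", "pos", "ref", "alt", "consequence"]
                              ).itertuples(index=False)}
        records = annotate_catalog(catalog, gencode, encode, rs, gene_model,
                                   gad, omim, regdb, csq)
        assert [r.locus.key for r in records] == [l.key for l in catalog]
        truth = study["track_truth"]
        for rec in records:
            t = truth[rec.locus.key]
            assert rec.gencode_biotypes == t["biotypes"]
            assert rec.encode_elements == t["encode"]
            assert rec.gerp_pass == t["gerp_pass"]
            assert rec.gad_classes == t["gad_classes"]
            assert rec.omim == t["omim"]
            assert rec.regulomedb_score == t["regulomedb_score"]
            assert rec.consequence == t["consequence"]

    def test_summary_conserves_class_totals(self, study, catalog):
        records = annotate_catalog(
            catalog, FeatureTrack([]), FeatureTrack([]), BedGraphTrack([]),
            FeatureTrack([]), pd.DataFrame(columns=["gene_id", "disease_class",
                                                    "association"]), set(), {})
        summary = summarize_catalog(records)
        totals = summary[summary.category == "total"]
        for cls in "ABCU":
            assert totals[cls].sum() == sum(1 for l in catalog if l.rra_class == cls)
        assert totals["all"].sum() == len(catalog)

    def test_empty_catalog_gives_empty_summary(self):
        assert summarize_catalog([]).empty

    def test_tsv_writer_emits_one_row_per_locus(self, tmp_path, catalog):
        records = annotate_catalog(
            catalog, FeatureTrack([]), FeatureTrack([]), BedGraphTrack([]),
            FeatureTrack([]), pd.DataFrame(columns=["gene_id", "disease_class",
                                                    "association"]), set(), {})
        out = tmp_path / "annot.tsv"
        write_annotation_tsv(str(out), records, header_comments=["test"])
        lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == len(catalog) + 1
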