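"""Catalog construction, allele-frequency filtering and class assignment."""

import itertools

import pandas as pd
import pytest

from rrascan.rra_catalog import (
    PanelRecord,
    UndefinedAFError,
    UnsupportedVariantError,
    build_catalog,
    classify_rra,
    classify_variant_type,
    compare_panels,
    compare_reference_alleles,
    compute_ref_af,
    locus_from_panel_record,
    population_presence,
    read_catalog_vcf,
    reference_update_tallies,
    sharing_category,
    write_catalog_vcf,
)

from _oracles import classify_oracle


def record_from_codes(codes, **kw):
    samples = [f"S{i}" for i in range(len(codes))]
    defaults = dict(chrom="chr1", pos=100, ref_allele="A", alt_alleles=["G"])
    defaults.update(kw)
    return PanelRecord(genotype_codes=list(codes), sample_ids=samples, **defaults)


class TestComputeRefAF:
    @pytest.mark.parametrize(
        "codes, expected",
        [
            ([2] * 1092, 0.0),
            ([1] * 21 + [2] * 1071, 21 / 2184),
            ([1] * 22 + [2] * 1070, 22 / 2184),
            ([0, 1, 2, None], 3 / 6),  # missing excluded from both sides
        ],
    )
    def test_hand_counts(self, codes, expected):
        assert compute_ref_af(record_from_codes(codes)) == pytest.approx(expected, abs=1e-12)

    def test_af_threshold_boundary(self):
        """21 ref alleles of 2184 pass the 1% filter; 22 fail."""
        assert compute_ref_af(record_from_codes([1] * 21 + [2] * 1071)) < 0.01
        assert compute_ref_af(record_from_codes([1] * 22 + [2] * 1070)) >= 0.01

    def test_all_missing_is_undefined(self):
        with pytest.raises(UndefinedAFError):
            compute_ref_af(record_from_codes([None, None, None]))


class TestVariantType:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [("A", "G", "SNV"), ("A", "AT", "INS"), ("AT", "A", "DEL"),
         ("A", "ATTT", "INS"), ("ACGT", "A", "DEL")],
    )
    def test_classification(self, ref, alt, expected):
        assert classify_variant_type(ref, alt) == expected

    def test_mnv_rejected(self):
        with pytest.raises(UnsupportedVariantError):
            classify_variant_type("AT", "GC")

    def test_empty_allele_rejected(self):
        with pytest.raises(ValueError):
            classify_variant_type("", "A")


class TestClassifyRRA:
    @pytest.mark.parametrize(
        "codes, expected",
        [
            ([2] * 10, "A"),
            ([1] * 5 + [2] * 1087, "B"),
            ([0] + [1] * 3 + [2] * 1088, "C"),
            ([0] + [2] * 9, "U"),  # hom-ref without het: outside A/B/C
            ([2, None, 2], "A"),  # missing does not create a carrier
        ],
    )
    def test_examples(self, codes, expected):
        assert classify_rra(record_from_codes(codes)) == expected

    def test_matches_scanning_oracle_exhaustively(self):
        """Exhaustive agreement with a vector-scanning oracle, lengths <= 4.

        (The full length-6 sweep runs in the acceptance suite.)
        """
        for length in range(1, 5):
            for codes in itertools.product([0, 1, 2, None], repeat=length):
                rec = record_from_codes(list(codes))
                assert classify_rra(rec) == classify_oracle(codes)


class TestPopulationPresence:
    def popmap(self, n, pops=("AFR", "AMR", "ASN", "EUR")):
        return {f"S{i}": pops[i % len(pops)] for i in range(n)}

    def test_class_a_has_no_carriers(self):
        rec = record_from_codes([2] * 8)
        assert population_presence(rec, self.popmap(8)) == frozenset()
        assert sharing_category(frozenset()) == "None"

    def test_private_and_shared(self):
        # S0 (AFR) het only -> private AFR
        rec = record_from_codes([1] + [2] * 7)
        pops = population_presence(rec, self.popmap(8))
        assert sharing_category(pops) == "AFR"
        # S0 (AFR) + S3 (EUR) -> Two Pop
        rec = record_from_codes([1, 2, 2, 1] + [2] * 4)
        assert sharing_category(population_presence(rec, self.popmap(8))) == "Two Pop"

    def test_unlabelled_sample_is_an_error(self):
        rec = record_from_codes([1, 2])
        with pytest.raises(KeyError):
            population_presence(rec, {"S1": "EUR"})

    def test_none_category_iff_class_a(self, catalog):
        for locus in catalog:
            assert (sharing_category(locus.pop_presence) == "None") == (
                locus.rra_class == "A"
            )


class TestBuildCatalog:
    def test_recovers_planted_rra_loci_exactly(self, study):
        truth = {(r["chrom"], r["pos"]): r for r in study["panel_truth_rows"]}
        planted = {k for k, r in truth.items() if r["is_rra"]}
        found = {(l.chrom, l.pos) for l in study["catalog"]}
        assert found == planted
        for locus in study["catalog"]:
            row = truth[(locus.chrom, locus.pos)]
            assert locus.rra_class == row["rra_class"]
            assert locus.ref_af == pytest.approx(row["ref_af"], abs=1e-12)
            assert locus.ref_af < 0.01

    def test_partition_and_counts_conserve_samples(self, study, catalog):
        n_samples = 1092
        for locus in catalog:
            assert locus.n_homref + locus.n_het + locus.n_homalt + locus.n_missing == n_samples
        classes = {c: sum(1 for l in catalog if l.rra_class == c) for c in "ABCU"}
        assert sum(classes.values()) == len(catalog)

    def test_threshold_monotonicity(self, study):
        """A catalog at a tighter AF threshold is a subset of a looser one."""
        tight = {l.key for l in build_catalog(study["panel_vcf"], af_threshold=0.003)}
        loose = {l.key for l in build_catalog(study["panel_vcf"], af_threshold=0.01)}
        assert tight <= loose

    def test_strict_threshold_comparison(self, study):
        """The AF filter is strictly 'smaller than': threshold 0 admits nothing."""
        assert build_catalog(study["panel_vcf"], af_threshold=0.0) == []

    def test_deterministic_order(self, study):
        loci = build_catalog(study["panel_vcf"])
        keys = [(l.chrom, l.pos) for l in loci]
        assert keys == sorted(keys, key=lambda k: (k[0], k[1]))


class TestCatalogVCFRoundTrip:
    def test_write_read_identity(self, tmp_path, study, catalog):
        path = str(tmp_path / "catalog.vcf")
        contigs = [("chr1", 60000), ("chr2", 30000)]
        write_catalog_vcf(path, catalog, contigs)
        back = read_catalog_vcf(path)
        assert len(back) == len(catalog)
        for a, b in zip(catalog, back):
            assert a.key == b.key
            assert a.rra_class == b.rra_class
            assert (a.n_homref, a.n_het, a.n_homalt, a.n_missing) == (
                b.n_homref, b.n_het, b.n_homalt, b.n_missing)
            assert a.pop_presence == b.pop_presence
            assert b.ref_af == pytest.approx(a.ref_af, rel=1e-5)


class TestComparePanels:
    def test_disjoint_panels_share_nothing(self, catalog):
        other = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "ref_af"])
        assert compare_panels(catalog, other) == (0, {0.01: 0, 0.03: 0, 0.05: 0})

    def test_planted_concordance_counts(self, catalog):
        rows = []
        for i, locus in enumerate(catalog[:5]):
            rows.append({"chrom": locus.chrom, "pos": locus.pos,
                         "ref": locus.ref_allele, "alt": locus.alt_allele,
                         "ref_af": 0.005 if i < 3 else 0.04})
        shared, below = compare_panels(catalog, pd.DataFrame(rows))
        assert shared == 5
        assert below[0.01] == 3
        assert below[0.05] == 5


class TestCompareReferenceAlleles:
    def test_identity_remap_is_all_unchanged(self, study, catalog):
        remap = {(l.chrom, l.pos): (l.chrom, l.pos) for l in catalog}
        result = compare_reference_alleles(catalog, remap, study["reference"])
        assert set(result["status"]) == {"unchanged"}

    def test_planted_edits_and_unmapped(self, tmp_path, study, catalog):
        """Edited bases are flagged updated; '-' remaps are unmappable."""
        import pyfaidx

        edited = tmp_path / "grch_next.fa"
        seqs = {r.name: str(r) for r in pyfaidx.Fasta(study["reference"])}
        targets = [l for l in catalog if l.variant_type == "SNV"][:3]
        chars = {c: list(s) for c, s in seqs.items()}
        for locus in targets:
            old = chars[locus.chrom][locus.pos - 1]
            chars[locus.chrom][locus.pos - 1] = "ACGT"[("ACGT".index(old) + 1) % 4]
        with open(edited, "w") as fh:
            for name, s in chars.items():
                fh.write(f">{name}\n" + "".join(s) + "\n")
        remap = {(l.chrom, l.pos): (l.chrom, l.pos) for l in catalog}
        unmapped = catalog[-1]
        remap[(unmapped.chrom, unmapped.pos)] = None
        result = compare_reference_alleles(catalog, remap, str(edited))
        by_status = result.groupby("status").size().to_dict()
        assert by_status["updated"] == 3
        assert by_status["unmappable"] == 1
        assert by_status["unchanged"] == len(catalog) - 4
        tallies = reference_update_tallies(result)
        assert tallies["count"].sum() == len(catalog)
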