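"""Build, classify and compare the catalog of rare-reference-allele (RRA) loci.

An RRA locus is a position where the reference assembly carries an allele
whose frequency in a large sequenced panel is below a threshold (default 1%),
so the "variant" most resequencing pipelines would report there is in fact
the common allele.  The catalog is built from a multi-sample population VCF
by reducing each sample's GT to a 0/1/2 non-reference dosage code, computing
the reference allele frequency, and classifying each passing locus:

* class A — the reference allele was never observed in the panel;
* class B — observed only in heterozygotes;
* class C — observed in both heterozygous and homozygous-reference state;
* class U — hom-ref carriers but no heterozygote (not covered by the A/B/C
  scheme; kept separate rather than folded into C).

Missing genotypes are excluded from both the allele-frequency denominator
and class assignment but are retained in ``n_missing``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

from .io_formats import (
    CATALOG_INFO_LINES,
    build_vcf_header,
    open_fasta,
    write_bed,
)

logger = logging.getLogger(__name__)

MISSING = None  # genotype-code sentinel for ./. calls

VALID_BASES = frozenset("ACGTN")


class UndefinedAFError(ValueError):
    """Allele frequency is undefined (no called genotypes)."""


class UnsupportedVariantError(ValueError):
    """Allele pair is not an SNV, insertion or deletion."""


class MissingGTError(ValueError):
    """VCF lacks the GT FORMAT field."""


@dataclass
class PanelRecord:
    """One population-VCF site reduced to per-sample non-ref dosage codes.

    ``genotype_codes[i]`` counts the non-reference alleles of sample
    ``sample_ids[i]``: 0 = hom-ref, 1 = het, 2 = hom-alt, ``None`` = missing.
    """

    chrom: str
    pos: int  # 1-based VCF POS
    ref_allele: str
    alt_alleles: list[str]
    genotype_codes: list[Optional[int]]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.genotype_codes) != len(self.sample_ids):
            raise ValueError("genotype_codes and sample_ids length mismatch")
        for allele in [self.ref_allele, *self.alt_alleles]:
            if not allele or set(allele.upper()) - VALID_BASES:
                raise ValueError(f"invalid allele {allele!r}")

    def genotype_counts(self) -> tuple[int, int, int, int]:
        """(n_homref, n_het, n_homalt, n_missing)."""
        n = [0, 0, 0, 0]
        for code in self.genotype_codes:
            n[3 if code is MISSING else code] += 1
        return tuple(n)


@dataclass
class RRALocus:
    """One catalog entry."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: list[str]
    variant_type: str  # SNV | INS | DEL
    ref_af: float
    n_homref: int
    n_het: int
    n_homalt: int
    n_missing: int
    rra_class: str  # A | B | C | U
    pop_presence: frozenset = field(default_factory=frozenset)

    @property
    def alt_allele(self) -> str:
        """Primary (first) alternative allele."""
        return self.alt_alleles[0]

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref_allele, tuple(self.alt_alleles))


# ---------------------------------------------------------------------------
# Elementary classification operations
# ---------------------------------------------------------------------------

def compute_ref_af(record: PanelRecord) -> float:
    """Reference allele count over total called allele count.

    Missing genotypes are excluded from numerator and denominator; an
    all-missing record has no defined frequency and raises
    :class:`UndefinedAFError`.
    """
    n_homref, n_het, n_homalt, _ = record.genotype_counts()
    called = n_homref + n_het + n_homalt
    if called == 0:
        raise UndefinedAFError(f"{record.chrom}:{record.pos}: all genotypes missing")
    return (2 * n_homref + n_het) / (2 * called)


def classify_variant_type(ref_allele: str, alt_allele: str) -> str:
    """SNV / INS / DEL by allele-length comparison; MNVs are rejected."""
    if not ref_allele or not alt_allele:
        raise ValueError("alleles must be non-empty")
    if len(ref_allele) == len(alt_allele):
        if len(ref_allele) == 1:
            return "SNV"
        raise UnsupportedVariantError(
            f"equal-length multi-base substitution {ref_allele}>{alt_allele}"
        )
    return "INS" if len(alt_allele) > len(ref_allele) else "DEL"


def classify_rra(record: PanelRecord) -> str:
    """Assign class A/B/C/U from the genotype-code vector."""
    n_homref, n_het, _, _ = record.genotype_counts()
    if n_homref == 0:
        return "A" if n_het == 0 else "B"
    return "C" if n_het > 0 else "U"


def population_presence(record: PanelRecord, popmap: Mapping[str, str]) -> frozenset:
    """Set of populations with at least one reference-allele carrier."""
    pops = set()
    for sample, code in zip(record.sample_ids, record.genotype_codes):
        if code in (0, 1):  # carries >= 1 reference allele
            try:
                pops.add(popmap[sample])
            except KeyError:
                raise KeyError(f"sample {sample!r} missing from population map") from None
    return frozenset(pops)


def sharing_category(pops: frozenset) -> str:
    """Summarize a presence set: None / private label / Two-Four Pop."""
    if not pops:
        return "None"
    if len(pops) == 1:
        return next(iter(pops))
    return {2: "Two Pop", 3: "Three Pop", 4: "Four Pop"}.get(len(pops), f"{len(pops)} Pop")


# ---------------------------------------------------------------------------
# Panel VCF -> catalog
# ---------------------------------------------------------------------------

def _dosage_code(gt: tuple, haploid_as_single_allele: bool = False) -> Optional[int]:
    """Reduce a GT tuple to a 0/1/2 non-ref dosage code (None = missing)."""
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return MISSING
    if len(gt) == 1:
        if not haploid_as_single_allele:
            return MISSING
        return min(gt[0], 1)
    return sum(1 for a in gt if a != 0)


def iter_panel_records(
    panel_vcf: str,
    haploid_as_single_allele: bool = False,
) -> Iterable[tuple[PanelRecord, Optional[str]]]:
    """Yield (record, skip_reason) per VCF site; skipped sites carry a reason."""
    vcf = pysam.VariantFile(panel_vcf)
    if "GT" not in vcf.header.formats:
        raise MissingGTError(f"{panel_vcf}: no GT FORMAT defined in header")
    samples = list(vcf.header.samples)
    if not samples:
        raise MissingGTError(f"{panel_vcf}: no samples in header")
    for rec in vcf:
        alts = [a for a in (rec.alts or ())]
        if not alts or any(a is None or a.startswith("<") or "[" in a or "]" in a for a in alts):
            yield None, f"{rec.chrom}:{rec.pos}: symbolic/missing ALT"
            continue
        try:
            codes = [
                _dosage_code(rec.samples[s].get("GT"), haploid_as_single_allele)
                for s in samples
            ]
            record = PanelRecord(rec.chrom, rec.pos, rec.ref, alts, codes, samples)
            # Reject MNV-style primary alleles up front.
            classify_variant_type(record.ref_allele, record.alt_alleles[0])
        except (ValueError, KeyError) as exc:
            yield None, f"{rec.chrom}:{rec.pos}: {exc}"
            continue
        yield record, None


def locus_from_panel_record(
    record: PanelRecord, popmap: Optional[Mapping[str, str]] = None
) -> RRALocus:
    n_homref, n_het, n_homalt, n_missing = record.genotype_counts()
    pops = population_presence(record, popmap) if popmap is not None else frozenset()
    return RRALocus(
        chrom=record.chrom,
        pos=record.pos,
        ref_allele=record.ref_allele,
        alt_alleles=list(record.alt_alleles),
        variant_type=classify_variant_type(record.ref_allele, record.alt_alleles[0]),
        ref_af=compute_ref_af(record),
        n_homref=n_homref,
        n_het=n_het,
        n_homalt=n_homalt,
        n_missing=n_missing,
        rra_class=classify_rra(record),
        pop_presence=pops,
    )


def build_catalog(
    panel_vcf: str,
    af_threshold: float = 0.01,
    popmap: Optional[Mapping[str, str]] = None,
    haploid_as_single_allele: bool = False,
) -> list[RRALocus]:
    """Scan a population VCF and emit every locus with ref AF < threshold.

    Output order is deterministic: chromosomes in input order, then by
    (pos, ref, alt).
    """
    loci: list[RRALocus] = []
    n_skipped = 0
    n_seen = 0
    chrom_order: dict[str, int] = {}
    for record, reason in iter_panel_records(panel_vcf, haploid_as_single_allele):
        if record is None:
            logger.info("build_catalog: skipping %s", reason)
            n_skipped += 1
            continue
        n_seen += 1
        chrom_order.setdefault(record.chrom, len(chrom_order))
        try:
            af = compute_ref_af(record)
        except UndefinedAFError as exc:
            logger.info("build_catalog: skipping %s", exc)
            n_skipped += 1
            continue
        if af < af_threshold:
            loci.append(locus_from_panel_record(record, popmap))
    loci.sort(key=lambda l: (chrom_order[l.chrom], l.pos, l.ref_allele, tuple(l.alt_alleles)))
    logger.info(
        "build_catalog: %d sites scanned, %d skipped, %d RRA loci (AF < %g)",
        n_seen, n_skipped, len(loci), af_threshold,
    )
    return loci


# ---------------------------------------------------------------------------
# Cross-panel and cross-assembly comparisons
# ---------------------------------------------------------------------------

def compare_panels(
    catalog: Sequence[RRALocus],
    other_panel_af: pd.DataFrame,
    thresholds: Sequence[float] = (0.01, 0.03, 0.05),
) -> tuple[int, dict[float, int]]:
    """Concordance of the catalog with another panel's reference AFs.

    ``other_panel_af`` is keyed by (chrom, pos, ref, alt) with a ``ref_af``
    column.  Returns (number of catalog loci found in the other panel,
    {threshold: number of shared loci with other-panel ref AF below it}).
    """
    table = {
        (str(r.chrom), int(r.pos), r.ref, r.alt): float(r.ref_af)
        for r in other_panel_af.itertuples(index=False)
    }
    shared = 0
    below = {t: 0 for t in thresholds}
    for locus in catalog:
        af = table.get((locus.chrom, locus.pos, locus.ref_allele, locus.alt_allele))
        if af is None:
            continue
        shared += 1
        for t in thresholds:
            if af < t:
                below[t] += 1
    return shared, below


def compare_reference_alleles(
    catalog: Sequence[RRALocus],
    remap_table: Mapping[tuple[str, int], Optional[tuple[str, int]]],
    new_reference_fasta: str,
) -> pd.DataFrame:
    """Compare catalog reference alleles against a newer assembly.

    ``remap_table`` maps old (chrom, 1-based pos) to new coordinates or None
    for unmapped loci (the remapping itself is an input, not computed here).
    Returns one row per locus with a status in {updated, unchanged,
    unmappable}.
    """
    fasta = open_fasta(new_reference_fasta)
    rows = []
    for locus in catalog:
        target = remap_table.get((locus.chrom, locus.pos))
        status = "unmappable"
        if target is not None:
            new_chrom, new_pos = target
            if new_chrom in fasta.references:
                start0 = new_pos - 1
                end0 = start0 + len(locus.ref_allele)
                if 0 <= start0 and end0 <= fasta.get_reference_length(new_chrom):
                    new_bases = fasta.fetch(new_chrom, start0, end0).upper()
                    status = "unchanged" if new_bases == locus.ref_allele.upper() else "updated"
        rows.append(
            {
                "chrom": locus.chrom,
                "pos": locus.pos,
                "ref": locus.ref_allele,
                "alt": locus.alt_allele,
                "variant_type": locus.variant_type,
                "rra_class": locus.rra_class,
                "status": status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "variant_type", "rra_class", "status"],
    )


def reference_update_tallies(comparison: pd.DataFrame) -> pd.DataFrame:
    """Per-variant-type counts of updated/unchanged/unmappable loci."""
    if comparison.empty:
        return pd.DataFrame(columns=["variant_type", "status", "count"])
    out = (
        comparison.groupby(["variant_type", "status"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_catalog_vcf(
    path: str,
    catalog: Sequence[RRALocus],
    contigs: Sequence[tuple[str, int]],
    meta_lines: Sequence[str] = (),
) -> None:
    """Write the catalog as a sites-only VCF with RRA_* INFO keys."""
    header = build_vcf_header(contigs, CATALOG_INFO_LINES, meta_lines=meta_lines)
    with pysam.VariantFile(path, "w", header=header) as out:
        for locus in catalog:
            rec = out.new_record(
                contig=locus.chrom,
                start=locus.pos - 1,
                alleles=(locus.ref_allele, *locus.alt_alleles),
            )
            rec.info["RRA_CLASS"] = locus.rra_class
            rec.info["RRA_AF"] = locus.ref_af
            rec.info["RRA_COUNTS"] = (
                locus.n_homref, locus.n_het, locus.n_homalt, locus.n_missing,
            )
            if locus.pop_presence:
                rec.info["RRA_POPS"] = tuple(sorted(locus.pop_presence))
            rec.info["RRA_TYPE"] = locus.variant_type
            out.write(rec)


def read_catalog_vcf(path: str) -> list[RRALocus]:
    """Read a catalog VCF written by :func:`write_catalog_vcf`."""
    loci = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            counts = rec.info["RRA_COUNTS"]
            loci.append(
                RRALocus(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=list(rec.alts),
                    variant_type=rec.info["RRA_TYPE"],
                    ref_af=float(rec.info["RRA_AF"]),
                    n_homref=counts[0],
                    n_het=counts[1],
                    n_homalt=counts[2],
                    n_missing=counts[3],
                    rra_class=rec.info["RRA_CLASS"],
                    pop_presence=frozenset(rec.info.get("RRA_POPS", ())),
                )
            )
    return loci


def write_catalog_bed(path: str, catalog: Sequence[RRALocus]) -> None:
    """BED (0-based half-open) covering each locus's affected reference span."""
    rows = []
    for locus in catalog:
        start = locus.pos - 1
        rows.append(
            (locus.chrom, start, start + len(locus.ref_allele),
             f"{locus.ref_allele}>{locus.alt_allele}", locus.rra_class)
        )
    write_bed(path, rows)
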