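"""Feature-overlap, conservation, regulatory and phenotype annotation of RRA loci.

Overlap semantics by variant type (internal 0-based half-open coordinates):

* SNV — the single affected base ``[pos-1, pos)``;
* DEL — the deleted span, which excludes the VCF anchor base: ``[pos, pos-1+len(ref))``;
* INS — the insertion point between the anchor base and the next one; the
  point must fall strictly inside a feature interval to count as overlap.

Threshold rules applied here:

* conservation (GERP RS): an SNV or insertion passes iff the RS score at its
  anchor position is strictly greater than 2; a deletion passes iff any
  deleted base has RS > 2;
* RegulomeDB: score <= 3 flags a locus as likely affecting TF binding.

Consequence classes (missense/nonsense/frameshift/splicing/synonymous) are
consumed from a precomputed table keyed by (chrom, pos, ref, alt); this
package does not predict consequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GenomicInterval

logger = logging.getLogger(__name__)

ENCODE_ELEMENTS = ("TFP", "DHS", "enhancer")
CONSEQUENCES = ("missense", "nonsense", "frameshift", "splicing", "synonymous",
                "non_exonic", "none")


@dataclass
class AnnotationRecord:
    locus: object
    gencode_biotypes: frozenset = frozenset()
    encode_elements: frozenset = frozenset()
    consequence: str = "none"
    gerp_pass: bool = False
    gad_classes: frozenset = frozenset()
    omim: bool = False
    regulomedb_score: Optional[int] = None

    @property
    def regulomedb_functional(self) -> bool:
        """RegulomeDB score <= 3: likely functional, affects TF binding."""
        return self.regulomedb_score is not None and self.regulomedb_score <= 3


class FeatureTrack:
    """Labelled intervals with interval-tree lookup (one tree per chromosome)."""

    def __init__(self, rows: Sequence[tuple]):
        """``rows``: (chrom, start, end, label, *extra); extra[0] (if present)
        is a group id (e.g. gene id) returned by :meth:`group_overlaps`."""
        self._trees: dict[str, IntervalTree] = {}
        for row in rows:
            chrom, start, end, label = row[0], int(row[1]), int(row[2]), row[3]
            group = row[4] if len(row) > 4 else None
            if end <= start:
                continue  # empty interval cannot be overlapped
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end, (label, group))

    @classmethod
    def from_bed(cls, rows: Sequence[tuple], label_col: int = 3, group_col: Optional[int] = None):
        out = []
        for row in rows:
            label = row[label_col] if len(row) > label_col else "."
            group = row[group_col] if group_col is not None and len(row) > group_col else None
            out.append((row[0], row[1], row[2], label, group))
        return cls(out)

    def _hits(self, locus) -> set:
        tree = self._trees.get(locus.chrom)
        if tree is None:
            return set()
        span = affected_span(locus)
        if locus.variant_type == "INS":
            point = span.start
            # insertion point strictly inside [s, e): s < point < e
            return {iv.data for iv in tree.at(point) if iv.begin < point}
        if span.start == span.end:
            return set()
        return {iv.data for iv in tree.overlap(span.start, span.end)}

    def overlapping_labels(self, locus) -> frozenset:
        return frozenset(label for label, _ in self._hits(locus))

    def overlapping_groups(self, locus) -> frozenset:
        return frozenset(group for _, group in self._hits(locus) if group is not None)


def affected_span(locus) -> GenomicInterval:
    """The reference span a variant affects (see module docstring)."""
    pos0 = locus.pos - 1
    if locus.variant_type == "SNV":
        return GenomicInterval(locus.chrom, pos0, pos0 + 1)
    if locus.variant_type == "DEL":
        return GenomicInterval(locus.chrom, pos0 + 1, pos0 + len(locus.ref_allele))
    if locus.variant_type == "INS":
        return GenomicInterval(locus.chrom, pos0 + 1, pos0 + 1)  # insertion point
    raise ValueError(f"unknown variant type {locus.variant_type!r}")


def overlap_features(loci: Sequence, tracks: Mapping[str, FeatureTrack]) -> dict:
    """Per-locus feature labels from each named track."""
    return {
        locus.key: {name: track.overlapping_labels(locus) for name, track in tracks.items()}
        for locus in loci
    }


def gerp_filter(locus, rs_track) -> bool:
    """Strict RS > 2 rule; deletions pass if any deleted base passes.

    Positions absent from the conservation track fail with a warning.
    """
    span = affected_span(locus)
    if locus.variant_type in ("SNV", "INS"):
        positions = [locus.pos - 1]  # anchor base
    else:
        positions = list(range(span.start, span.end))
    scores = [rs_track.value_at(locus.chrom, p) for p in positions]
    if all(s is None for s in scores):
        logger.warning("gerp_filter: %s:%d absent from RS track", locus.chrom, locus.pos)
        return False
    return any(s is not None and s > 2.0 for s in scores)


def join_phenotypes(
    locus,
    gene_model: FeatureTrack,
    gad_table: pd.DataFrame,
    omim_genes: set,
    regdb_scores: Mapping[tuple[str, int], int],
) -> tuple[frozenset, bool, Optional[int]]:
    """(gad_classes, omim flag, regulomedb score) for one locus.

    GAD classes are the union over overlapped genes of disease classes with
    a positive (Y) association; records without a Y flag are ignored.
    """
    genes = gene_model.overlapping_groups(locus)
    gad_classes: set = set()
    if genes and len(gad_table):
        positive = gad_table[gad_table["association"] == "Y"]
        gad_classes = set(positive[positive["gene_id"].isin(genes)]["disease_class"])
    omim = bool(genes & omim_genes)
    score = regdb_scores.get((locus.chrom, locus.pos))
    return frozenset(gad_classes), omim, score


def annotate_catalog(
    loci: Sequence,
    gencode: FeatureTrack,
    encode: FeatureTrack,
    rs_track,
    gene_model: FeatureTrack,
    gad_table: pd.DataFrame,
    omim_genes: set,
    regdb_scores: Mapping[tuple[str, int], int],
    consequences: Mapping[tuple, str] = None,
) -> list[AnnotationRecord]:
    """Attach every annotation layer to each locus (the locus set is unchanged)."""
    consequences = consequences or {}
    records = []
    for locus in loci:
        gad_classes, omim, score = join_phenotypes(
            locus, gene_model, gad_table, omim_genes, regdb_scores
        )
        records.append(
            AnnotationRecord(
                locus=locus,
                gencode_biotypes=gencode.overlapping_labels(locus),
                encode_elements=encode.overlapping_labels(locus) & set(ENCODE_ELEMENTS),
                consequence=consequences.get(
                    (locus.chrom, locus.pos, locus.ref_allele, locus.alt_allele), "none"
                ),
                gerp_pass=gerp_filter(locus, rs_track),
                gad_classes=gad_classes,
                omim=omim,
                regulomedb_score=score,
            )
        )
    return records


def summarize_catalog(annotated: Sequence[AnnotationRecord]) -> pd.DataFrame:
    """Cross-tabulate loci by variant type x class x annotation category.

    Categories follow the usual reporting layout: total, GENCODE (any
    biotype), protein-coding, non-coding RNA, pseudogene, ENCODE elements,
    conserved (RS > 2), functional consequence.  A locus can contribute to
    several rows, so annotation rows need not sum to the total row.
    """
    ncRNA_biotypes = {"lincRNA", "antisense", "processed_transcript", "miRNA",
                      "snoRNA", "snRNA", "ncRNA"}
    functional = {"missense", "nonsense", "frameshift", "splicing"}

    def categories(rec: AnnotationRecord):
        yield "total"
        if rec.gencode_biotypes:
            yield "gencode"
        if "protein_coding" in rec.gencode_biotypes:
            yield "protein_coding"
        if rec.gencode_biotypes & ncRNA_biotypes:
            yield "ncRNA"
        if any("pseudogene" in b for b in rec.gencode_biotypes):
            yield "pseudogene"
        if rec.encode_elements:
            yield "encode"
        if rec.gerp_pass:
            yield "conserved"
        if rec.consequence in functional:
            yield "functional"

    counts: dict[tuple[str, str, str], int] = {}
    for rec in annotated:
        vt, cls = rec.locus.variant_type, rec.locus.rra_class
        for cat in categories(rec):
            key = (vt, cat, cls)
            counts[key] = counts.get(key, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["variant_type", "category", "A", "B", "C", "U", "all"])
    rows = {}
    for (vt, cat, cls), count in counts.items():
        rows.setdefault((vt, cat), {"A": 0, "B": 0, "C": 0, "U": 0})[cls] = count
    out = []
    for (vt, cat), by_class in sorted(rows.items()):
        out.append({
            "variant_type": vt, "category": cat, **by_class,
            "all": sum(by_class.values()),
        })
    return pd.DataFrame(out, columns=["variant_type", "category", "A", "B", "C", "U", "all"])


ANNOTATION_TSV_COLUMNS = (
    "chrom", "pos", "ref", "alt", "variant_type", "rra_class", "biotypes",
    "encode_elements", "consequence", "gerp_pass", "gad_classes", "omim",
    "regulomedb_score",
)


def write_annotation_tsv(path: str, annotated: Sequence[AnnotationRecord],
                         header_comments: Sequence[str] = ()) -> None:
    def fmt_set(s):
        return ",".join(sorted(s)) if s else "."

    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"#{comment}\n")
        fh.write("\t".join(ANNOTATION_TSV_COLUMNS) + "\n")
        for rec in annotated:
            locus = rec.locus
            fh.write("\t".join(str(x) for x in (
                locus.chrom, locus.pos, locus.ref_allele, locus.alt_allele,
                locus.variant_type, locus.rra_class,
                fmt_set(rec.gencode_biotypes), fmt_set(rec.encode_elements),
                rec.consequence, int(rec.gerp_pass), fmt_set(rec.gad_classes),
                int(rec.omim),
                rec.regulomedb_score if rec.regulomedb_score is not None else ".",
            )) + "\n")
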