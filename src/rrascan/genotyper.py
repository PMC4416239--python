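"""Forced-allele diploid genotyping at catalog loci from aligned reads.

At every catalog locus the caller considers exactly the two supplied alleles
(the rare reference allele and the common alternative) and computes diploid
genotype likelihoods from the pileup — no allele discovery.  Every locus
yields a record, including zero-coverage no-calls (EMIT_ALL_SITES
semantics).

Observation model, per read with Phred base quality Q and error probability
e = 10^(-Q/10):

* SNV: P(base | true allele) = 1 - e if the base matches, e/3 otherwise;
* InDel: binary event support (insertion/deletion present or absent in the
  read's alignment at the locus) with P = 1 - e / e, where Q is the minimum
  base quality over the event plus one flanking base on each side.

For a diploid genotype g = a1/a2 each read contributes
P(obs|g) = (P(obs|a1) + P(obs|a2)) / 2, and log10 L(g) sums over reads.
Posteriors use the standard theta-based diploid site prior
(hom-ref 1 - 3*theta/2, het theta, hom-alt theta/2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pysam

from .io_formats import build_vcf_header

logger = logging.getLogger(__name__)

GENOTYPES = ("ref/ref", "ref/alt", "alt/alt")

#: Upper clamp for Phred-scaled qualities (keeps VCF output finite).
MAX_PHRED = 9999.0


@dataclass(frozen=True)
class ReadObservation:
    """A single read's evidence at one locus."""

    allele_support: str  # "ref" | "alt" | "other"
    base_quality: int
    mapping_quality: int

    def __post_init__(self) -> None:
        if self.base_quality < 0 or self.mapping_quality < 0:
            raise ValueError("qualities must be >= 0")


@dataclass
class PileupColumn:
    locus: object
    observations: list[ReadObservation] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.observations)

    @property
    def allele_depths(self) -> tuple[int, int]:
        ref = sum(1 for o in self.observations if o.allele_support == "ref")
        alt = sum(1 for o in self.observations if o.allele_support == "alt")
        return ref, alt


@dataclass
class GenotypeCall:
    sample_id: str
    locus: object
    genotype: Optional[tuple[str, str]]  # e.g. ("ref", "alt"); None = no-call
    log10_likelihoods: Optional[tuple[float, float, float]]
    genotype_quality: float
    site_qual: float
    allele_depths: tuple[int, int]
    depth: int = 0

    @property
    def is_no_call(self) -> bool:
        return self.genotype is None

    def contains_reference_allele(self) -> bool:
        return self.genotype is not None and "ref" in self.genotype

    @property
    def zygosity(self) -> Optional[str]:
        if self.genotype is None:
            return None
        return "hom" if self.genotype[0] == self.genotype[1] else "het"


# ---------------------------------------------------------------------------
# Pileup construction
# ---------------------------------------------------------------------------

def _snv_observation(read: pysam.AlignedSegment, locus) -> Optional[tuple[str, int]]:
    pos0 = locus.pos - 1
    for qpos, rpos in read.get_aligned_pairs():
        if rpos == pos0:
            if qpos is None:  # deletion over the site: no base to score
                return None
            base = read.query_sequence[qpos].upper()
            qual = read.query_qualities[qpos]
            if base == locus.ref_allele.upper():
                return "ref", qual
            if base == locus.alt_allele.upper():
                return "alt", qual
            return "other", qual
    return None


def _indel_observation(read: pysam.AlignedSegment, locus) -> Optional[tuple[str, int]]:
    """Binary event support for an insertion or deletion at the locus.

    INS (ref len 1): alt-supporting reads carry inserted bases between the
    anchor base and the next reference base; ref-supporting reads align both
    contiguously.  DEL: alt-supporting reads delete the span after the
    anchor; ref-supporting reads align every base of the span.  Reads that
    do not fully span the event are uninformative.
    """
    pos0 = locus.pos - 1
    ref_len = len(locus.ref_allele)
    alt_len = len(locus.alt_allele)
    is_insertion = alt_len > ref_len
    span_end = pos0 + ref_len - 1  # last reference base of the REF allele
    pairs = read.get_aligned_pairs()
    by_ref = {rpos: qpos for qpos, rpos in pairs if rpos is not None}
    quals = read.query_qualities

    anchor_q = by_ref.get(pos0)
    if anchor_q is None:
        return None

    if is_insertion:
        next_q = by_ref.get(pos0 + 1)
        if next_q is None:
            return None  # read ends or is deleted at the junction
        inserted = [qpos for qpos, rpos in pairs
                    if rpos is None and qpos is not None and anchor_q < qpos < next_q]
        event_qpos = [anchor_q, *inserted, next_q]
        support = "alt" if inserted else "ref"
        return support, min(quals[q] for q in event_qpos)

    # Deletion: reference span pos0+1 .. span_end deleted in the alt allele.
    span = range(pos0 + 1, span_end + 1)
    aligned = [by_ref.get(r) for r in span]
    covered = {rpos for _, rpos in pairs if rpos is not None}
    if not all(r in covered for r in span):
        return None  # read does not span the whole event
    after_q = by_ref.get(span_end + 1)
    if all(q is None for q in aligned):
        if after_q is None:
            return None
        return "alt", min(quals[anchor_q], quals[after_q])
    if all(q is not None for q in aligned):
        flank = [after_q] if after_q is not None else []
        return "ref", min(quals[q] for q in [anchor_q, *aligned, *flank])
    return "other", quals[anchor_q]  # partial deletion of the span


def pileup(
    alignments: pysam.AlignmentFile,
    locus,
    min_base_quality: int = 13,
    min_mapping_quality: int = 20,
) -> PileupColumn:
    """Collect filtered read observations for the locus's forced alleles.

    Duplicates, unmapped/secondary/supplementary/QC-fail reads and reads
    below the quality thresholds are excluded.  Overlapping mates are
    counted once, keeping the higher-base-quality observation.
    """
    if locus.chrom not in alignments.references:
        raise KeyError(f"contig {locus.chrom!r} absent from alignment header")
    is_snv = locus.variant_type == "SNV"
    pos0 = locus.pos - 1
    fetch_end = pos0 + len(locus.ref_allele)
    best: dict[str, ReadObservation] = {}
    for read in alignments.fetch(locus.chrom, pos0, fetch_end):
        if (read.is_unmapped or read.is_duplicate or read.is_secondary
                or read.is_supplementary or read.is_qcfail):
            continue
        if read.mapping_quality < min_mapping_quality:
            continue
        result = (_snv_observation if is_snv else _indel_observation)(read, locus)
        if result is None:
            continue
        support, qual = result
        if qual < min_base_quality:
            continue
        obs = ReadObservation(support, int(qual), read.mapping_quality)
        prev = best.get(read.query_name)
        if prev is None or obs.base_quality > prev.base_quality:
            best[read.query_name] = obs
    observations = [best[name] for name in sorted(best)]
    return PileupColumn(locus=locus, observations=observations)


# ---------------------------------------------------------------------------
# Likelihoods and posteriors
# ---------------------------------------------------------------------------

def _allele_probs(obs: ReadObservation, is_snv: bool) -> tuple[float, float]:
    """P(observation | true allele) for (ref, alt)."""
    e = 10.0 ** (-obs.base_quality / 10.0)
    mismatch = e / 3.0 if is_snv else e
    p_ref = 1.0 - e if obs.allele_support == "ref" else mismatch
    p_alt = 1.0 - e if obs.allele_support == "alt" else mismatch
    return p_ref, p_alt


def genotype_likelihoods(
    column: PileupColumn, is_snv: Optional[bool] = None
) -> tuple[float, float, float]:
    """log10 likelihoods for (ref/ref, ref/alt, alt/alt)."""
    if column.depth == 0:
        raise ValueError("no observations: no-call")
    if is_snv is None:
        is_snv = getattr(column.locus, "variant_type", "SNV") == "SNV"
    ll = [0.0, 0.0, 0.0]
    for obs in column.observations:
        p_ref, p_alt = _allele_probs(obs, is_snv)
        ll[0] += math.log10(p_ref)
        ll[1] += math.log10(0.5 * p_ref + 0.5 * p_alt)
        ll[2] += math.log10(p_alt)
    return tuple(ll)


def _phred(p: float) -> float:
    if p <= 0.0:
        return MAX_PHRED
    return min(MAX_PHRED, -10.0 * math.log10(p))


def call_genotype(
    likelihoods: tuple[float, float, float],
    prior_heterozygosity: float = 0.001,
    sample_id: str = "",
    locus=None,
    allele_depths: tuple[int, int] = (0, 0),
    depth: int = 0,
) -> GenotypeCall:
    """MAP diploid genotype under the theta-based site prior.

    * genotype_quality: Phred of 1 - (max normalized posterior);
    * site_qual: hom-ref-versus-rest confidence on the Phred scale — for a
      non-reference call the Phred of P(hom-ref), for a hom-ref call the
      Phred of 1 - P(hom-ref) (reference-confidence emission, so confident
      calls of either kind score high);
    * exact posterior ties break toward the heterozygote.
    """
    theta = prior_heterozygosity
    priors = (1.0 - 1.5 * theta, theta, 0.5 * theta)
    log_post = [ll + math.log10(p) for ll, p in zip(likelihoods, priors)]
    scale = max(log_post)
    weights = [10.0 ** (lp - scale) for lp in log_post]
    total = sum(weights)
    posteriors = [w / total for w in weights]
    # argmax with het-preferring deterministic tie-break
    best = max(posteriors)
    for idx in (1, 0, 2):
        if posteriors[idx] == best:
            call_idx = idx
            break
    genotype = (("ref", "ref"), ("ref", "alt"), ("alt", "alt"))[call_idx]
    p_homref = posteriors[0]
    site_qual = _phred(1.0 - p_homref) if call_idx == 0 else _phred(p_homref)
    return GenotypeCall(
        sample_id=sample_id,
        locus=locus,
        genotype=genotype,
        log10_likelihoods=tuple(likelihoods),
        genotype_quality=_phred(1.0 - posteriors[call_idx]),
        site_qual=site_qual,
        allele_depths=allele_depths,
        depth=depth,
    )


def no_call(sample_id: str, locus) -> GenotypeCall:
    return GenotypeCall(
        sample_id=sample_id,
        locus=locus,
        genotype=None,
        log10_likelihoods=None,
        genotype_quality=0.0,
        site_qual=0.0,
        allele_depths=(0, 0),
    )


def genotype_targets(
    alignments: pysam.AlignmentFile,
    catalog: Sequence,
    sample_id: str = "sample",
    min_base_quality: int = 13,
    min_mapping_quality: int = 20,
    prior_heterozygosity: float = 0.001,
) -> list[GenotypeCall]:
    """Forced-allele genotype of every catalog locus (one record per locus)."""
    calls = []
    for locus in catalog:
        column = pileup(alignments, locus, min_base_quality, min_mapping_quality)
        if column.depth == 0:
            calls.append(no_call(sample_id, locus))
            continue
        ll = genotype_likelihoods(column)
        calls.append(
            call_genotype(
                ll,
                prior_heterozygosity=prior_heterozygosity,
                sample_id=sample_id,
                locus=locus,
                allele_depths=column.allele_depths,
                depth=column.depth,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

GENOTYPER_FORMAT_LINES = (
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref,alt)">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Filtered depth">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">',
)

_GT_CODES = {("ref", "ref"): (0, 0), ("ref", "alt"): (0, 1), ("alt", "alt"): (1, 1)}


def write_calls_vcf(
    path: str,
    calls: Sequence[GenotypeCall],
    contigs: Sequence[tuple[str, int]],
    sample_id: str,
    info_lines: Sequence[str] = (),
    info_values: Optional[Sequence[dict]] = None,
    meta_lines: Sequence[str] = (),
) -> None:
    """One-sample VCF with GT/AD/DP/GQ/PL and site QUAL per call."""
    header = build_vcf_header(
        contigs, info_lines, GENOTYPER_FORMAT_LINES, [sample_id], meta_lines
    )
    with pysam.VariantFile(path, "w", header=header) as out:
        for i, call in enumerate(calls):
            locus = call.locus
            rec = out.new_record(
                contig=locus.chrom,
                start=locus.pos - 1,
                alleles=(locus.ref_allele, locus.alt_allele),
            )
            rec.qual = round(min(call.site_qual, MAX_PHRED), 2)
            sample = rec.samples[sample_id]
            sample["GT"] = _GT_CODES.get(call.genotype, (None, None))
            sample["AD"] = call.allele_depths
            sample["DP"] = call.depth
            sample["GQ"] = int(round(min(call.genotype_quality, MAX_PHRED)))
            if call.log10_likelihoods is not None:
                best = max(call.log10_likelihoods)
                sample["PL"] = tuple(
                    int(round(min(-10.0 * (ll - best), MAX_PHRED)))
                    for ll in call.log10_likelihoods
                )
            if info_values is not None:
                for key, value in info_values[i].items():
                    rec.info[key] = value
            out.write(rec)
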