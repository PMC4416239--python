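"""Germline and somatic calling on top of forced-allele genotype calls.

Germline mode keeps, per sample, every genotype call that (a) reaches the
site-quality threshold (default Phred 30, error rate < 0.1%) and (b)
contains at least one copy of the rare reference allele (het or hom-ref).

Somatic mode compares matched normal/tumor calls at each locus: a candidate
somatic event requires the normal genotype to contain *no* reference allele
while the tumor genotype contains at least one.  Candidates are then tested
with a two-sided Fisher exact test on the 2x2 table of post-filter allele
depths [[normal_ref, normal_alt], [tumor_ref, tumor_alt]] and accepted when
p < alpha (default 0.01).

The Fisher test uses the probability-ordering two-sided definition (sum the
hypergeometric probabilities of all tables with the observed margins that
are no more probable than the observed table), computed with exact integer
arithmetic so ties are handled exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .genotyper import GenotypeCall

logger = logging.getLogger(__name__)


@dataclass
class SomaticCall:
    locus: object
    normal_allele_depths: tuple[int, int]
    tumor_allele_depths: tuple[int, int]
    fisher_p: Optional[float]
    verdict: str  # "somatic_rra" | "rejected"
    reason: str = ""


# ---------------------------------------------------------------------------
# Fisher exact test (2x2, two-sided, probability ordering)
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table: Sequence[Sequence[int]], alternative: str = "two-sided") -> float:
    """Exact p-value for a 2x2 contingency table [[a, b], [c, d]].

    Under fixed margins, P(a) is hypergeometric.  Integer weights
    w(x) = C(r1, x) * C(r2, c1 - x) share the denominator C(n, c1), so the
    two-sided probability ordering ("at least as extreme" = "no more
    probable") is decided by exact integer comparison — no floating-point
    tie ambiguity.  An all-zero table has p = 1 by convention.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    if n == 0:
        logger.warning("fisher_exact_2x2: all-zero table, p = 1 by convention")
        return 1.0
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    total = sum(weights)
    w_obs = weights[a - lo]
    if alternative == "two-sided":
        tail = sum(w for w in weights if w <= w_obs)
    elif alternative == "less":
        tail = sum(weights[: a - lo + 1])
    elif alternative == "greater":
        tail = sum(weights[a - lo:])
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return min(1.0, tail / total)


# ---------------------------------------------------------------------------
# Germline mode
# ---------------------------------------------------------------------------

def germline_filter(calls: Sequence[GenotypeCall], min_qual: float = 30.0) -> list[GenotypeCall]:
    """Retain reference-allele-carrying calls at or above the quality bar.

    Records are never modified — the output is a filtered subset of the
    input, in input order.
    """
    kept = [
        call
        for call in calls
        if not call.is_no_call
        and call.site_qual >= min_qual
        and call.contains_reference_allele()
    ]
    logger.info("germline_filter: %d of %d calls retained (QUAL >= %g, ref-carrying)",
                len(kept), len(calls), min_qual)
    return kept


# ---------------------------------------------------------------------------
# Somatic mode
# ---------------------------------------------------------------------------

def somatic_compare(
    normal_call: GenotypeCall,
    tumor_call: GenotypeCall,
    alpha: float = 0.01,
    alternative: str = "two-sided",
) -> SomaticCall:
    """Classify one matched normal/tumor locus.

    Candidate iff the normal genotype carries no reference allele and the
    tumor genotype carries at least one; candidates become ``somatic_rra``
    when the Fisher p-value on the paired allele depths is below ``alpha``.
    """
    if normal_call.locus is None or tumor_call.locus is None or (
        normal_call.locus.key != tumor_call.locus.key
    ):
        raise ValueError("somatic_compare: normal and tumor calls are at different loci")
    locus = normal_call.locus
    n_ad, t_ad = normal_call.allele_depths, tumor_call.allele_depths

    def rejected(reason: str, p: Optional[float] = None) -> SomaticCall:
        return SomaticCall(locus, n_ad, t_ad, p, "rejected", reason)

    if normal_call.is_no_call or tumor_call.is_no_call:
        return rejected("no-call in pair")
    if normal_call.contains_reference_allele():
        return rejected("reference allele present in normal")
    if not tumor_call.contains_reference_allele():
        return rejected("reference allele absent in tumor")
    p = fisher_exact_2x2([list(n_ad), list(t_ad)], alternative=alternative)
    if p < alpha:
        return SomaticCall(locus, n_ad, t_ad, p, "somatic_rra", "")
    return rejected(f"fisher p {p:.4g} >= {alpha:g}", p)


def somatic_compare_all(
    normal_calls: Sequence[GenotypeCall],
    tumor_calls: Sequence[GenotypeCall],
    alpha: float = 0.01,
    alternative: str = "two-sided",
) -> list[SomaticCall]:
    if len(normal_calls) != len(tumor_calls):
        raise ValueError("normal and tumor call lists differ in length")
    return [
        somatic_compare(n, t, alpha=alpha, alternative=alternative)
        for n, t in zip(normal_calls, tumor_calls)
    ]


# ---------------------------------------------------------------------------
# End-to-end drivers
# ---------------------------------------------------------------------------

def run_germline(
    alignments_per_sample: dict,
    catalog: Sequence,
    contigs: Sequence[tuple[str, int]],
    out_vcf_per_sample: dict,
    min_qual: float = 30.0,
    min_base_quality: int = 13,
    min_mapping_quality: int = 20,
    meta_lines: Sequence[str] = (),
) -> dict[str, list[GenotypeCall]]:
    """Genotype + germline-filter each sample; write one VCF per sample.

    Samples are processed independently (no joint re-calling).  Returns the
    retained calls per sample.
    """
    from .genotyper import genotype_targets, write_calls_vcf

    results: dict[str, list[GenotypeCall]] = {}
    for sample_id, alignments in alignments_per_sample.items():
        calls = genotype_targets(
            alignments, catalog, sample_id,
            min_base_quality=min_base_quality,
            min_mapping_quality=min_mapping_quality,
        )
        kept = germline_filter(calls, min_qual=min_qual)
        info_values = [
            {
                "RRA_CLASS": c.locus.rra_class,
                "RRA_TYPE": c.locus.variant_type,
                "RRA_AF": c.locus.ref_af,
                "ZYG": c.zygosity,
            }
            for c in kept
        ]
        info_lines = (
            '##INFO=<ID=RRA_CLASS,Number=1,Type=String,Description="RRA class (A/B/C/U)">',
            '##INFO=<ID=RRA_TYPE,Number=1,Type=String,Description="Variant type">',
            '##INFO=<ID=RRA_AF,Number=1,Type=Float,Description="Panel reference allele frequency">',
            '##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity of the reference allele (het/hom)">',
        )
        write_calls_vcf(
            out_vcf_per_sample[sample_id], kept, contigs, sample_id,
            info_lines=info_lines, info_values=info_values, meta_lines=meta_lines,
        )
        results[sample_id] = kept
    return results


SOMATIC_TSV_COLUMNS = (
    "chrom", "pos", "ref", "alt", "variant_type", "rra_class",
    "normal_AD", "tumor_AD", "fisher_p",
)


def run_somatic(
    normal_alignments,
    tumor_alignments,
    catalog: Sequence,
    out_tsv: str,
    alpha: float = 0.01,
    min_qual: float = 30.0,
    min_base_quality: int = 13,
    min_mapping_quality: int = 20,
    alternative: str = "two-sided",
    header_comments: Sequence[str] = (),
) -> list[SomaticCall]:
    """Somatic mode for one matched pair; writes accepted calls as TSV.

    The quality bar applies to the tumor call (the sample asserted to carry
    the reference allele).
    """
    from .genotyper import genotype_targets

    normal_calls = genotype_targets(
        normal_alignments, catalog, "normal",
        min_base_quality=min_base_quality, min_mapping_quality=min_mapping_quality,
    )
    tumor_calls = genotype_targets(
        tumor_alignments, catalog, "tumor",
        min_base_quality=min_base_quality, min_mapping_quality=min_mapping_quality,
    )
    somatic = []
    for n_call, t_call in zip(normal_calls, tumor_calls):
        if not t_call.is_no_call and t_call.site_qual < min_qual:
            somatic.append(SomaticCall(
                n_call.locus, n_call.allele_depths, t_call.allele_depths,
                None, "rejected", f"tumor QUAL below {min_qual:g}",
            ))
            continue
        somatic.append(somatic_compare(n_call, t_call, alpha=alpha, alternative=alternative))
    accepted = [s for s in somatic if s.verdict == "somatic_rra"]
    with open(out_tsv, "w") as fh:
        for comment in header_comments:
            fh.write(f"#{comment}\n")
        fh.write("\t".join(SOMATIC_TSV_COLUMNS) + "\n")
        for s in accepted:
            locus = s.locus
            fh.write("\t".join(str(x) for x in (
                locus.chrom, locus.pos, locus.ref_allele, locus.alt_allele,
                locus.variant_type, locus.rra_class,
                f"{s.normal_allele_depths[0]},{s.normal_allele_depths[1]}",
                f"{s.tumor_allele_depths[0]},{s.tumor_allele_depths[1]}",
                f"{s.fisher_p:.6g}",
            )) + "\n")
    logger.info("run_somatic: %d of %d loci accepted as somatic RRA (alpha=%g)",
                len(accepted), len(catalog), alpha)
    return somatic
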