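# Methods

## The problem

A haploid reference assembly is a mosaic of a few anonymous donors, so it
inevitably carries some alleles that are rare in the population — including
positions where the reference base has never been seen in homozygous state in
any sequenced individual. At such a rare-reference-allele (RRA) locus the
roles of "reference" and "variant" are inverted: the common allele shows up
as a variant call in every sample, and the rare allele of interest is the
reference base itself. Standard germline callers cannot report it, common
AF-based filters (drop known variants with AF > 1%) remove the heterozygous
signal, and somatic callers subtract it away when the matched normal is
homozygous for the common alternative. This package builds the catalog of
such loci from a population panel and re-genotypes them explicitly.

## Catalog model

Each panel VCF site is reduced to per-sample non-reference dosage codes
(0 = hom-ref, 1 = het, 2 = hom-alt, missing). Multi-allelic GTs count any
non-reference allele toward the dosage, matching the common 0/1/2 matrix
encoding of population panels. The reference allele frequency is

    AF_ref = (2·n_homref + n_het) / (2·(n_homref + n_het + n_homalt)),

with missing genotypes excluded from numerator and denominator (an
all-missing site has undefined AF and is skipped with a log message). The
catalog keeps loci with AF_ref strictly below the threshold (default 0.01;
strict comparison, so 21/2184 passes and 22/2184 fails at 1092 samples).

Classes partition every catalog: **A** n_homref = n_het = 0; **B**
n_homref = 0, n_het > 0; **C** n_homref > 0 and n_het > 0; **U**
n_homref > 0, n_het = 0. Class U covers genotype vectors the three-class
scheme does not (reference seen homozygous but never heterozygous); we keep
it distinct rather than folding it into C because C is defined by observing
*both* states. Population presence is the set of populations with at least
one dosage-0/1 sample; it is empty exactly for class A.

Variant types are SNV/INS/DEL by allele-length comparison. Equal-length
multi-base substitutions (MNVs) are outside the model and raise a dedicated
error; the catalog builder skips such records with a counted log entry.
Haploid GTs are treated as missing by default (an opt-in flag counts them as
a single allele). Structural/symbolic ALTs are skipped.

Cross-assembly comparison takes a precomputed coordinate remap table as
input (computing the remap is out of scope) and labels each locus
updated / unchanged / unmappable by comparing the catalog REF against the
new assembly's bases at the remapped coordinates.

## Sequence-context screen

To check whether catalog loci concentrate in hard-to-sequence contexts, the
100-bp window centered on each locus (anchor base at index `size // 2`,
left-biased; clamped-and-flagged at contig edges) is scored for GC fraction
— (G+C)/(A+C+G+T), case-insensitive, N bases excluded from the denominator
(all-N windows are missing rather than zero) — and mean per-base
mappability from a bedGraph/bigWig track, with uncovered bases counting 0
under a logged warning. Background windows are sampled uniformly over all
valid start positions genome-wide from a seeded generator, so per-contig
counts are proportional to contig length in expectation.

## Forced-allele genotyper

The genotyper replaces an external joint caller with an in-repo model whose
every constant is visible. It considers exactly the catalog's ref/alt pair
at each locus and emits a record per site (no-calls included), i.e.
EMIT-ALL-SITES, GENOTYPE-GIVEN-ALLELES semantics. Numerical parity with any
particular external caller is a non-goal.

**Pileup.** Reads that are unmapped, duplicate, secondary, supplementary or
QC-fail are excluded, as are reads under MAPQ 20 or base quality 13 (all
configurable). Overlapping mates are counted once, keeping the
higher-quality observation. SNV support is the aligned base at POS; reads
with a deletion over the site are uninformative. InDel support is binary —
event present/absent in the read's alignment at the locus — and only reads
that fully span the event (plus its right flank for insertions) are
informative. The InDel observation quality is the minimum base quality over
the event ± one flanking base: a simple, testable stand-in for
realignment-based error models.

**Likelihoods.** Per read with error probability e = 10^(−Q/10):
P(obs|allele) = 1−e if the read supports that allele, else e/3 for SNVs
(three possible wrong bases) or e for InDels (binary event). A diploid
genotype a1/a2 mixes alleles evenly: P(obs|g) = ½P(obs|a1) + ½P(obs|a2);
log10 L(g) sums over reads. The test suite checks log-space sums against a
linear-space product oracle to 1e−9 relative on pileups ≤ 15 reads.

**Posteriors.** Site prior from heterozygosity θ = 0.001: hom-ref 1−3θ/2,
het θ, hom-alt θ/2. The call is the MAP genotype; exact posterior ties
break toward the heterozygote (conservative for the downstream
reference-allele filters, and deterministic). GQ is the Phred of
1 − max posterior.

**Site quality.** `site_qual` is the hom-ref-versus-rest confidence: for a
non-reference call the Phred of P(hom-ref); for a hom-ref call the Phred of
1 − P(hom-ref). This is reference-confidence emission: a confident call of
*either* kind scores high, so a single QUAL ≥ 30 threshold (error rate
< 0.1%) is meaningful for both the heterozygous and the
homozygous-reference RRA calls that germline mode must retain. Defining
site_qual as P(hom-ref) unconditionally would drive the quality of every
confident hom-ref call to ~0 and silently delete the homozygous half of the
germline output. Phred values are clamped at 9999.

## Germline and somatic calling

Germline mode filters, never edits: it keeps calls with site_qual ≥ 30
whose genotype contains ≥ 1 reference allele, annotates zygosity and the
locus class, and writes one VCF per sample; samples are independent. All
ref-carrying calls are emitted with class labels (including hom-ref calls
at class-C loci) so downstream users can filter on class.

Somatic mode judges presence/absence of the reference allele on the called
genotypes (mirroring genotype-based somatic subtraction), then tests the
read counts: candidate iff normal carries no reference allele and tumor
carries at least one; the 2×2 table [[normal_ref, normal_alt],
[tumor_ref, tumor_alt]] of post-filter allele depths is tested with a
two-sided Fisher exact test and accepted at p < 0.01. Two-sided is the
default because the test is a direction-agnostic difference check (a
one-sided variant is available via `--one-sided`); the tumor call must also
pass the site-quality bar. No-calls and mismatched loci reject/raise.

The Fisher p-value uses the probability-ordering definition: sum the
hypergeometric probabilities of all tables with the observed margins that
are no more probable than the observed table. It is computed with exact
integer weights w(x) = C(r1, x)·C(r2, c1−x) over the common denominator
C(n, c1), so the "no more probable" comparison is exact integer comparison
and ties carry no floating-point ambiguity; the all-zero table is p = 1 by
convention. The suite verifies exact (≤ 1e−12) agreement with an
independent factorial-product rational-arithmetic enumeration over every
table with total ≤ 60, and cross-checks against scipy's implementation.

## Annotation rules

Overlap spans: SNV = its single base; deletion = the deleted span (the VCF
anchor base is not deleted and is excluded); insertion = the insertion
point between the anchor and the next base, which must fall strictly inside
a feature interval. Conservation: SNVs and insertions pass iff RS at the
anchor base is strictly > 2; deletions pass iff any deleted base is > 2;
positions absent from the track fail with a warning. GAD joins use only
records with a positive (Y) association flag; OMIM is a gene-set membership
flag; RegulomeDB scores ≤ 3 (inclusive) flag likely TF-binding impact.
Gene overlap counts any transcript-span intersection (an exon-only mode is
not implemented; intron/UTR overlaps count). Annotation never changes the
locus set, and the summary cross-tabulation's per-class totals equal the
catalog's class partition; a locus can contribute to several annotation
rows (set semantics).

## Synthetic data: what it emulates and what it does not

The generator mirrors the structure of a 1092-sample panel across four
macro-populations (AFR 246, AMR 181, ASN 286, EUR 379). Defaults: 100 loci
(20 class A, 30 B with 1–10 het carriers, 10 C with one hom-ref plus 1–8
hets, 40 non-RRA with ref AF ≥ 0.05 via ~8% hom-ref + ~10% het samples),
SNV/INS/DEL cycling with 1–3 bp InDels, ~0.2% missing genotypes placed only
among hom-alt samples so planted classes are untouched, read depth 40 at
Q30 with 100-bp reads, and a two-contig 90-kb reference. Class C requires
> 150 samples at the 1% threshold (3 ref alleles / 2n < 0.01); the config
validates feasibility and raises otherwise. All randomness flows from one
seed; identical seeds give byte-identical files.

Simulated reads have uniform quality, perfect mapping (MAPQ 60), no
duplicates, no mate pairs, and exact planted CIGARs. Passing the planted
tests therefore demonstrates correctness of the genotype/statistics
machinery, not robustness to alignment artifacts, mapping ambiguity,
contamination or realistic error profiles — those are explicitly outside
the generator's scope. Heterozygous pileups draw each read's allele as a
fair Bernoulli, so het recovery is a distributional (not exact) property;
at depth 30–40 and Q30 misclassification probability is ~2^−29 per locus,
which is why the end-to-end tests can demand 100% recovery at the chosen
problem sizes (60 catalog loci, 600 simulated pileups).

## Numerical and design choices

* Coordinates are 0-based half-open internally; the VCF 1-based conversion
  lives in one io module and nowhere else. Chromosome names are matched
  strictly as given.
* Catalog output order is deterministic: input chromosome order, then
  (pos, ref, alt).
* Phred clamping at 9999; log-sum-exp style scaling before posterior
  normalization.
* Window "surrounding" a locus means centered (left-biased for even sizes);
  centering is configurable since other conventions exist.
* bedGraph is the native track format; bigWig is accepted through an
  optional reader (`pyBigWig`).
* Plain-text SAM fixtures are converted to sorted, indexed BAM on the fly
  for random access; the text SAM remains the source of truth.
* GC denominator excludes N bases by default (the alternative total-length
  convention used by some tools can be had by treating missing as 0).

## Limitations

* One alternative allele per locus record in the genotyper; multi-allelic
  forced genotyping is not supported (the catalog stores the full ALT list,
  the primary ALT drives typing).
* No local realignment or haplotype assembly; InDel support is purely
  CIGAR-based.
* The cross-assembly comparison depends entirely on the supplied remap
  table; unmapped or out-of-bounds targets are counted, not resolved.
* Consequence prediction, regulatory scoring, enrichment and driver-gene
  analyses are consumed as inputs where applicable, never computed.
* Full-scale population panels are supported by the same code paths but the
  shipped tests and the acceptance script run at the toy scale described
  above.
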