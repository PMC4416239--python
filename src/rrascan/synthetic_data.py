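"""Synthetic inputs with planted ground truth, at toy scale.

Everything the pipeline consumes can be generated here: a reference FASTA, a
multi-sample population VCF with planted rare-reference-allele classes, a
sample/population map, aligned reads (SAM) with planted genotypes, and all
annotation tracks (gene/biotype BED, regulatory-element BED, per-base
conservation bedGraph, mappability bedGraph, gene-phenotype and
locus-score TSVs).  A truth table records what was planted so tests can
round-trip the full pipeline without external downloads.

The panel emulates the structure of a 1092-sample, four-macro-population
panel: class A loci have no reference-allele carrier, class B loci carry
1-10 heterozygotes, class C loci one homozygous-reference sample plus at
least one heterozygote, and non-RRA loci have reference AF well above the
1% threshold.  All randomness flows from the single ``seed``.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pysam

from .genotyper import PileupColumn, ReadObservation
from .io_formats import build_vcf_header, open_fasta

BASES = "ACGT"

#: macro-population sample counts of the emulated 1092-sample panel
DEFAULT_POPULATION_FRACTIONS = {
    "AFR": 246 / 1092,
    "AMR": 181 / 1092,
    "ASN": 286 / 1092,
    "EUR": 379 / 1092,
}


class InfeasibleConfigError(ValueError):
    """The requested panel cannot realize the planted classes."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; the defaults are the study conditions."""

    n_samples: int = 1092
    population_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_POPULATION_FRACTIONS)
    )
    n_class_a: int = 20
    n_class_b: int = 30
    n_class_c: int = 10
    n_non_rra: int = 40
    class_b_het_range: tuple[int, int] = (1, 10)
    class_c_het_range: tuple[int, int] = (1, 8)
    non_rra_homref_fraction: float = 0.08
    non_rra_het_fraction: float = 0.10
    missing_fraction: float = 0.002
    af_threshold: float = 0.01
    read_depth: int = 40
    base_quality: int = 30
    read_length: int = 100
    mapping_quality: int = 60
    somatic_fraction: float = 0.1
    contigs: tuple = (("chr1", 60000), ("chr2", 30000))
    locus_spacing: int = 400
    seed: int = 1

    def __post_init__(self) -> None:
        total = sum(self.population_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise InfeasibleConfigError("population fractions must sum to 1")
        if self.n_samples < 1:
            raise InfeasibleConfigError("need at least one sample")
        # Feasibility of the planted classes under the AF threshold.
        max_alleles = 2 * self.n_samples
        if self.n_class_b and self.class_b_het_range[0] / max_alleles >= self.af_threshold:
            raise InfeasibleConfigError("class B infeasible: minimum het count exceeds AF threshold")
        if self.n_class_c and (2 + self.class_c_het_range[0]) / max_alleles >= self.af_threshold:
            raise InfeasibleConfigError(
                f"class C infeasible with {self.n_samples} samples at AF < {self.af_threshold}"
            )

    @property
    def n_loci(self) -> int:
        return self.n_class_a + self.n_class_b + self.n_class_c + self.n_non_rra

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["contigs"] = tuple(tuple(c) for c in raw.get("contigs", cls.contigs))
        for key in ("class_b_het_range", "class_c_het_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def population_counts(config: SimulationConfig) -> dict[str, int]:
    """Integer per-population sample counts (largest-remainder rounding)."""
    items = sorted(config.population_fractions.items())
    raw = [(name, config.n_samples * frac) for name, frac in items]
    counts = {name: int(x) for name, x in raw}
    short = config.n_samples - sum(counts.values())
    for name, _ in sorted(raw, key=lambda t: t[1] - int(t[1]), reverse=True)[:short]:
        counts[name] += 1
    return counts


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

def simulate_reference(config: SimulationConfig, path: str) -> str:
    """Random reference FASTA over the configured contigs (indexed on write)."""
    rng = np.random.default_rng(config.seed)
    with open(path, "w") as fh:
        for name, length in config.contigs:
            seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
            fh.write(f">{name}\n")
            for i in range(0, length, 70):
                fh.write(seq[i:i + 70] + "\n")
    pysam.faidx(path)
    return path


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

def _locus_positions(config: SimulationConfig) -> list[tuple[str, int]]:
    """Deterministic locus anchors, spaced along contigs proportionally."""
    margin = 200  # keep windows and reads clear of contig edges
    slots = []
    for name, length in config.contigs:
        pos = margin
        while pos < length - margin:
            slots.append((name, pos + 1))  # 1-based
            pos += config.locus_spacing
    if len(slots) < config.n_loci:
        raise InfeasibleConfigError(
            f"contigs hold {len(slots)} locus slots < {config.n_loci} requested"
        )
    return slots[: config.n_loci]


def _alleles_for(fasta: pysam.FastaFile, chrom: str, pos: int, vtype: str,
                 rng: np.random.Generator) -> tuple[str, str]:
    """(ref, alt) consistent with the reference sequence at a 1-based pos."""
    anchor = fasta.fetch(chrom, pos - 1, pos).upper()
    if vtype == "SNV":
        alt = BASES[(BASES.index(anchor) + 1 + rng.integers(0, 3)) % 4]
        return anchor, alt
    if vtype == "INS":
        ins_len = int(rng.integers(1, 4))
        inserted = "".join(np.array(list(BASES))[rng.integers(0, 4, size=ins_len)])
        return anchor, anchor + inserted
    del_len = int(rng.integers(1, 4))
    ref = fasta.fetch(chrom, pos - 1, pos - 1 + 1 + del_len).upper()
    return ref, anchor


def simulate_panel(
    config: SimulationConfig,
    reference_fasta: str,
    panel_vcf: str,
    popmap_tsv: str,
    truth_tsv: str,
) -> list[dict]:
    """Write the population VCF, population map and truth table.

    Returns the truth rows (one dict per locus).  The genotype vector of
    each locus realizes its planted class exactly; carriers are assigned to
    random samples so population sharing varies across loci.
    """
    rng = np.random.default_rng(config.seed + 1)
    fasta = open_fasta(reference_fasta)
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    pops = population_counts(config)
    pop_of: dict[str, str] = {}
    i = 0
    for name in sorted(pops):
        for _ in range(pops[name]):
            pop_of[samples[i]] = name
            i += 1

    with open(popmap_tsv, "w") as fh:
        for s in samples:
            fh.write(f"{s}\t{pop_of[s]}\n")

    class_plan = (
        ["A"] * config.n_class_a + ["B"] * config.n_class_b
        + ["C"] * config.n_class_c + ["non"] * config.n_non_rra
    )
    rng.shuffle(class_plan)
    vtypes = ["SNV", "INS", "DEL"]
    positions = _locus_positions(config)

    header = build_vcf_header(
        config.contigs,
        format_lines=('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',),
        samples=samples,
    )
    truth_rows: list[dict] = []
    with pysam.VariantFile(panel_vcf, "w", header=header) as vcf:
        for idx, ((chrom, pos), cls) in enumerate(zip(positions, class_plan)):
            vtype = vtypes[idx % 3]
            ref, alt = _alleles_for(fasta, chrom, pos, vtype, rng)
            codes = np.full(config.n_samples, 2, dtype=int)  # hom-alt baseline
            if cls == "B":
                n_het = int(rng.integers(config.class_b_het_range[0],
                                         config.class_b_het_range[1] + 1))
                carriers = rng.choice(config.n_samples, size=n_het, replace=False)
                codes[carriers] = 1
            elif cls == "C":
                n_het = int(rng.integers(config.class_c_het_range[0],
                                         config.class_c_het_range[1] + 1))
                carriers = rng.choice(config.n_samples, size=n_het + 1, replace=False)
                codes[carriers[0]] = 0
                codes[carriers[1:]] = 1
            elif cls == "non":
                n_homref = max(1, round(config.non_rra_homref_fraction * config.n_samples))
                n_het = max(1, round(config.non_rra_het_fraction * config.n_samples))
                carriers = rng.choice(config.n_samples, size=n_homref + n_het, replace=False)
                codes[carriers[:n_homref]] = 0
                codes[carriers[n_homref:]] = 1
            # Missing genotypes only among hom-alt samples so the planted
            # class and carrier set are untouched.
            n_missing = round(config.missing_fraction * config.n_samples)
            if n_missing:
                homalt_idx = np.flatnonzero(codes == 2)
                missing = rng.choice(homalt_idx, size=min(n_missing, len(homalt_idx)),
                                     replace=False)
                codes = codes.astype(object)
                codes[missing] = None

            rec = vcf.new_record(contig=chrom, start=pos - 1, alleles=(ref, alt))
            gt_of = {0: (0, 0), 1: (0, 1), 2: (1, 1), None: (None, None)}
            for s, code in zip(samples, codes):
                rec.samples[s]["GT"] = gt_of[code if code is None else int(code)]
            vcf.write(rec)

            called = [c for c in codes if c is not None]
            n0 = sum(1 for c in called if c == 0)
            n1 = sum(1 for c in called if c == 1)
            ref_af = (2 * n0 + n1) / (2 * len(called))
            carrier_pops = sorted(
                {pop_of[samples[i]] for i in range(config.n_samples)
                 if codes[i] in (0, 1)}
            )
            truth_rows.append({
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "variant_type": vtype,
                "rra_class": cls if cls != "non" else ".",
                "is_rra": int(cls != "non"),
                "ref_af": ref_af, "n_homref": n0, "n_het": n1,
                "n_missing": sum(1 for c in codes if c is None),
                "carrier_pops": ",".join(carrier_pops) if carrier_pops else ".",
            })

    with open(truth_tsv, "w") as fh:
        cols = list(truth_rows[0].keys())
        fh.write("\t".join(cols) + "\n")
        for row in truth_rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    return truth_rows


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def _read_for_allele(
    fasta: pysam.FastaFile, locus, allele: str, start0: int, read_length: int
) -> tuple[str, list[tuple[int, int]]]:
    """(sequence, cigartuples) of a read starting at ``start0`` carrying
    the locus's ref or alt allele.  Ref-allele reads match the reference
    exactly; alt-allele reads carry the substitution/insertion/deletion."""
    chrom, pos0 = locus.chrom, locus.pos - 1
    if allele == "ref":
        seq = fasta.fetch(chrom, start0, start0 + read_length).upper()
        return seq, [(0, read_length)]
    vtype = locus.variant_type
    if vtype == "SNV":
        seq = list(fasta.fetch(chrom, start0, start0 + read_length).upper())
        seq[pos0 - start0] = locus.alt_allele
        return "".join(seq), [(0, read_length)]
    if vtype == "INS":
        inserted = locus.alt_allele[1:]
        left = fasta.fetch(chrom, start0, pos0 + 1).upper()
        right_len = read_length - len(left) - len(inserted)
        right = fasta.fetch(chrom, pos0 + 1, pos0 + 1 + right_len).upper()
        cigar = [(0, len(left)), (1, len(inserted)), (0, right_len)]
        return left + inserted + right, cigar
    # DEL: skip the deleted span after the anchor base
    d = len(locus.ref_allele) - 1
    left = fasta.fetch(chrom, start0, pos0 + 1).upper()
    right_len = read_length - len(left)
    right = fasta.fetch(chrom, pos0 + 1 + d, pos0 + 1 + d + right_len).upper()
    cigar = [(0, len(left)), (2, d), (0, right_len)]
    return left + right, cigar


def simulate_reads(
    reference_fasta: str,
    genotypes: Mapping[tuple, str],
    loci: Sequence,
    out_sam: str,
    depth: int = 40,
    base_quality: int = 30,
    read_length: int = 100,
    mapping_quality: int = 60,
    seed: int = 0,
    sample_id: str = "sample",
) -> str:
    """Write a coordinate-sorted SAM with planted genotypes at catalog loci.

    ``genotypes`` maps ``locus.key`` to one of homref/het/homalt; loci
    absent from the mapping get no reads (zero coverage).  Homozygous
    pileups are pure; heterozygous pileups draw each read's allele as a
    fair Bernoulli.
    """
    rng = np.random.default_rng(seed)
    fasta = open_fasta(reference_fasta)
    contigs = [(c, fasta.get_reference_length(c)) for c in fasta.references]
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs],
        "RG": [{"ID": sample_id, "SM": sample_id}],
    }
    tid = {name: i for i, (name, _) in enumerate(contigs)}
    reads = []
    for locus in loci:
        gt = genotypes.get(locus.key)
        if gt is None:
            continue
        pos0 = locus.pos - 1
        event_len = max(len(locus.ref_allele), 2)
        lo = max(0, pos0 - (read_length - event_len - 15))
        hi = pos0 - 15  # anchor at least 15 bases into the read
        for i in range(depth):
            start0 = int(rng.integers(lo, hi + 1))
            if gt == "homref":
                allele = "ref"
            elif gt == "homalt":
                allele = "alt"
            else:
                allele = "ref" if rng.random() < 0.5 else "alt"
            seq, cigar = _read_for_allele(fasta, locus, allele, start0, read_length)
            reads.append((tid[locus.chrom], start0, seq, cigar,
                          f"{sample_id}:{locus.chrom}:{locus.pos}:{i}"))
    reads.sort(key=lambda r: (r[0], r[1], r[4]))
    with pysam.AlignmentFile(out_sam, "w", header=header) as out:
        for rtid, start0, seq, cigar, name in reads:
            aln = pysam.AlignedSegment(out.header)
            aln.query_name = name
            aln.query_sequence = seq
            aln.reference_id = rtid
            aln.reference_start = start0
            aln.mapping_quality = mapping_quality
            aln.cigartuples = cigar
            aln.query_qualities = pysam.qualitystring_to_array(
                chr(base_quality + 33) * len(seq)
            )
            aln.flag = 0
            aln.set_tag("RG", sample_id)
            out.write(aln)
    return out_sam


def simulate_pileup(
    genotype: str,
    depth: int,
    base_quality: int,
    rng: np.random.Generator,
    mapping_quality: int = 60,
) -> PileupColumn:
    """In-memory pileup with a planted genotype (no alignment round-trip)."""
    observations = []
    for _ in range(depth):
        if genotype == "homref":
            support = "ref"
        elif genotype == "homalt":
            support = "alt"
        else:
            support = "ref" if rng.random() < 0.5 else "alt"
        observations.append(ReadObservation(support, base_quality, mapping_quality))
    return PileupColumn(locus=None, observations=observations)


# ---------------------------------------------------------------------------
# Annotation tracks
# ---------------------------------------------------------------------------

#: planted per-locus annotation cycle (index modulo the cycle length)
ENCODE_CYCLE = ((), ("TFP",), ("DHS", "enhancer"), ("TFP", "DHS", "enhancer"))
CONSEQUENCE_CYCLE = ("missense", "nonsense", "frameshift", "splicing", "synonymous")
GAD_CLASS_CYCLE = (("CANCER",), ("IMMUNE", "METABOLIC"), ())


def simulate_tracks(config: SimulationConfig, loci: Sequence, out_dir: str) -> dict:
    """Deterministic annotation tracks with planted overlaps per locus.

    Every second locus sits in a gene (protein_coding or lincRNA
    alternating); regulatory elements, conservation scores, phenotype joins
    and RegulomeDB scores cycle deterministically so the planted truth is a
    pure function of the locus index.  Returns paths plus the planted truth
    per locus key.
    """
    paths = {name: os.path.join(out_dir, fname) for name, fname in [
        ("gencode", "gencode.bed"), ("encode", "encode.bed"),
        ("gerp", "gerp.bedgraph"), ("mappability", "mappability.bedgraph"),
        ("gad", "gad.tsv"), ("omim", "omim.tsv"),
        ("regulomedb", "regulomedb.tsv"), ("consequence", "consequence.tsv"),
    ]}
    gencode_rows, encode_rows, gerp_rows = [], [], []
    gad_lines, omim_lines, regdb_lines, csq_lines = [], [], [], []
    truth: dict[tuple, dict] = {}

    for idx, locus in enumerate(sorted(loci, key=lambda l: l.key)):
        pos0 = locus.pos - 1
        in_gene = idx % 2 == 0
        biotype = "protein_coding" if idx % 4 == 0 else "lincRNA"
        gene_id = f"GENE{idx:03d}"
        if in_gene:
            gencode_rows.append((locus.chrom, pos0 - 50, pos0 + 50, biotype, gene_id))
        elements = ENCODE_CYCLE[idx % len(ENCODE_CYCLE)]
        for el in elements:
            encode_rows.append((locus.chrom, pos0 - 20, pos0 + 20, el))
        # conservation: cycle pass / strict-boundary fail / fail
        if locus.variant_type == "DEL":
            span = range(pos0 + 1, pos0 + len(locus.ref_allele))
            per_base = [1.0] * len(span)
            gerp_pass = idx % 3 == 0
            if gerp_pass:
                per_base[-1] = 2.3  # any-base rule
            for p, v in zip(span, per_base):
                gerp_rows.append((locus.chrom, p, p + 1, v))
        else:
            rs = (2.5, 2.0, 0.5)[idx % 3]
            gerp_pass = rs > 2.0
            gerp_rows.append((locus.chrom, pos0, pos0 + 1, rs))
        gad_classes = GAD_CLASS_CYCLE[idx % len(GAD_CLASS_CYCLE)] if in_gene else ()
        for cls in gad_classes:
            gad_lines.append(f"{gene_id}\t{cls}\tY")
        if in_gene and idx % 3 == 1:
            gad_lines.append(f"{gene_id}\tVISION\tN")  # must be ignored (no Y flag)
        omim = in_gene and idx % 8 == 0
        if omim:
            omim_lines.append(f"{gene_id}\tplanted_phenotype")
        score = (idx % 6) + 1
        regdb_lines.append(f"{locus.chrom}\t{locus.pos}\t{score}")
        consequence = "none"
        if in_gene and biotype == "protein_coding":
            consequence = CONSEQUENCE_CYCLE[idx % len(CONSEQUENCE_CYCLE)]
            csq_lines.append(
                f"{locus.chrom}\t{locus.pos}\t{locus.ref_allele}\t{locus.alt_allele}\t{consequence}"
            )
        truth[locus.key] = {
            "biotypes": frozenset([biotype]) if in_gene else frozenset(),
            "genes": frozenset([gene_id]) if in_gene else frozenset(),
            "encode": frozenset(elements),
            "gerp_pass": gerp_pass,
            "gad_classes": frozenset(gad_classes),
            "omim": omim,
            "regulomedb_score": score,
            "consequence": consequence,
        }

    def write_rows(path, rows):
        with open(path, "w") as fh:
            for row in sorted(rows):
                fh.write("\t".join(str(x) for x in row) + "\n")

    write_rows(paths["gencode"], gencode_rows)
    write_rows(paths["encode"], encode_rows)
    write_rows(paths["gerp"], gerp_rows)
    mapp_rows = []
    for name, length in config.contigs:
        mapp_rows.append((name, 0, length // 2, 1.0))
        mapp_rows.append((name, length // 2, length, 0.5))
    write_rows(paths["mappability"], mapp_rows)
    with open(paths["gad"], "w") as fh:
        fh.write("gene_id\tdisease_class\tassociation\n")
        fh.write("\n".join(sorted(gad_lines)) + ("\n" if gad_lines else ""))
    with open(paths["omim"], "w") as fh:
        fh.write("gene_id\tphenotype\n")
        fh.write("\n".join(sorted(omim_lines)) + ("\n" if omim_lines else ""))
    with open(paths["regulomedb"], "w") as fh:
        fh.write("chrom\tpos\tscore\n")
        fh.write("\n".join(regdb_lines) + ("\n" if regdb_lines else ""))
    with open(paths["consequence"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\tconsequence\n")
        fh.write("\n".join(csq_lines) + ("\n" if csq_lines else ""))
    paths["truth"] = truth
    return paths


# ---------------------------------------------------------------------------
# Whole-study orchestration
# ---------------------------------------------------------------------------

def plant_germline_genotypes(loci: Sequence) -> dict[tuple, str]:
    """Deterministic per-locus genotypes for a germline sample: a mix of
    hom-ref, het and hom-alt (index cycle)."""
    cycle = ("het", "homalt", "homref")
    return {locus.key: cycle[i % 3] for i, locus in enumerate(loci)}


def plant_somatic_pair(loci: Sequence, somatic_fraction: float) -> tuple[dict, dict, set]:
    """(normal genotypes, tumor genotypes, somatic locus keys).

    The normal sample is homozygous for the common allele everywhere; the
    tumor gains the rare reference allele (het) at every ``1/somatic_fraction``-th
    locus.
    """
    normal = {locus.key: "homalt" for locus in loci}
    tumor = dict(normal)
    stride = max(1, round(1 / somatic_fraction)) if somatic_fraction > 0 else len(loci) + 1
    somatic_keys = set()
    for i, locus in enumerate(loci):
        if somatic_fraction > 0 and i % stride == 0:
            tumor[locus.key] = "het"
            somatic_keys.add(locus.key)
    return normal, tumor, somatic_keys


def simulate_study(config: SimulationConfig, out_dir: str) -> dict:
    """Generate the full input set for one synthetic study under ``out_dir``."""
    from .rra_catalog import build_catalog  # deferred: avoids import cycle

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "reference": os.path.join(out_dir, "reference.fa"),
        "panel_vcf": os.path.join(out_dir, "panel.vcf"),
        "popmap": os.path.join(out_dir, "popmap.tsv"),
        "truth": os.path.join(out_dir, "truth_loci.tsv"),
        "config": os.path.join(out_dir, "sim_config.json"),
    }
    config.to_json(paths["config"])
    simulate_reference(config, paths["reference"])
    truth_rows = simulate_panel(
        config, paths["reference"], paths["panel_vcf"], paths["popmap"], paths["truth"]
    )
    from .io_formats import read_population_map

    catalog = build_catalog(
        paths["panel_vcf"], af_threshold=config.af_threshold,
        popmap=read_population_map(paths["popmap"]),
    )
    track_paths = simulate_tracks(config, catalog, out_dir)
    paths.update({k: v for k, v in track_paths.items() if k != "truth"})
    paths["track_truth"] = track_paths["truth"]

    germline_gts = plant_germline_genotypes(catalog)
    normal_gts, tumor_gts, somatic_keys = plant_somatic_pair(catalog, config.somatic_fraction)
    for name, gts, sub_seed in (
        ("germline", germline_gts, 11), ("normal", normal_gts, 12), ("tumor", tumor_gts, 13),
    ):
        paths[f"{name}_sam"] = simulate_reads(
            paths["reference"], gts, catalog, os.path.join(out_dir, f"{name}.sam"),
            depth=config.read_depth, base_quality=config.base_quality,
            read_length=config.read_length, mapping_quality=config.mapping_quality,
            seed=config.seed + sub_seed, sample_id=name,
        )
    paths["germline_truth_genotypes"] = germline_gts
    paths["somatic_truth_keys"] = somatic_keys
    paths["panel_truth_rows"] = truth_rows
    paths["catalog"] = catalog
    return paths
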