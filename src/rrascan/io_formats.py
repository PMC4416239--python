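"""Readers and writers for the standard genomic text formats the pipeline touches.

All internal coordinates are 0-based half-open intervals.  The single place
where VCF's 1-based positions are converted to internal coordinates (and
back) is this module; nothing else in the package does coordinate arithmetic
between conventions.

Heavy-format access (VCF, SAM/BAM, FASTA) is delegated to pysam/pyfaidx;
line-oriented formats (BED, bedGraph, TSV tables) are parsed here.
"""

from __future__ import annotations

import gzip
import logging
import os
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)


class MalformedFileError(ValueError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start


def vcf_pos_to_interval(chrom: str, pos: int, ref_len: int = 1) -> GenomicInterval:
    """Convert a 1-based VCF POS (+ REF length) to the internal interval."""
    if pos < 1:
        raise ValueError(f"VCF POS must be >= 1, got {pos}")
    return GenomicInterval(chrom, pos - 1, pos - 1 + ref_len)


def interval_to_vcf_pos(interval: GenomicInterval) -> int:
    """Inverse of :func:`vcf_pos_to_interval` for the anchor base."""
    return interval.start + 1


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def read_bed(path: str, on_error: str = "fail") -> list[tuple]:
    """Read a BED file into (chrom, start, end, *extra_fields) tuples.

    ``on_error`` is either ``"fail"`` (raise on a malformed data line) or
    ``"skip"`` (log and continue).
    """
    rows: list[tuple] = []
    skipped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                if start > end:
                    raise ValueError("start > end")
            except (IndexError, ValueError) as exc:
                if on_error == "fail":
                    raise MalformedFileError(f"{path}:{lineno}: {exc}") from exc
                skipped += 1
                continue
            rows.append((chrom, start, end, *fields[3:]))
    if skipped:
        logger.warning("read_bed(%s): skipped %d malformed lines", path, skipped)
    return rows


def write_bed(path: str, rows: Iterable[Sequence], header_comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"#{comment}\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


class BedGraphTrack:
    """Per-base numeric track backed by bedGraph intervals (bigWig optional).

    Lookup returns ``None`` for bases not covered by any interval, so callers
    can distinguish "absent from track" from a genuine zero.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int, float]]):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in intervals:
            per_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        self._starts: dict[str, list[int]] = {}
        self._rows: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            for (s1, e1, _), (s2, _, _) in zip(rows, rows[1:]):
                if s2 < e1:
                    raise MalformedFileError(
                        f"overlapping bedGraph intervals on {chrom} at {s2}"
                    )
            self._rows[chrom] = rows
            self._starts[chrom] = [r[0] for r in rows]

    @classmethod
    def load(cls, path: str) -> "BedGraphTrack":
        if str(path).endswith((".bw", ".bigwig", ".bigWig")):
            return cls._load_bigwig(path)
        rows = []
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise MalformedFileError(f"{path}:{lineno}: expected 4 columns")
                rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
        return cls(rows)

    @classmethod
    def _load_bigwig(cls, path: str) -> "BedGraphTrack":
        import pyBigWig  # optional dependency

        rows = []
        with pyBigWig.open(path) as bw:
            for chrom, length in bw.chroms().items():
                for start, end, value in bw.intervals(chrom, 0, length) or []:
                    rows.append((chrom, start, end, value))
        return cls(rows)

    def value_at(self, chrom: str, pos0: int) -> Optional[float]:
        """Track value at a single 0-based position, or None if uncovered."""
        starts = self._starts.get(chrom)
        if not starts:
            return None
        i = bisect_right(starts, pos0) - 1
        if i < 0:
            return None
        start, end, value = self._rows[chrom][i]
        return value if start <= pos0 < end else None

    def values(self, interval: GenomicInterval) -> list[Optional[float]]:
        """Per-base values over an interval (None for uncovered bases)."""
        return [self.value_at(interval.chrom, p) for p in range(interval.start, interval.end)]


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_tsv_table(path: str, schema: Sequence[str]) -> pd.DataFrame:
    """Read a headered TSV and check it carries at least the ``schema`` columns."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise MalformedFileError(f"{path}: missing required columns {missing}")
    return df


def read_population_map(path: str) -> dict[str, str]:
    """2-column TSV (sample_id, population) -> dict; no header required."""
    popmap: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise MalformedFileError(f"{path}:{lineno}: expected 2 columns")
            if fields[0] in popmap and popmap[fields[0]] != fields[1]:
                raise MalformedFileError(f"{path}:{lineno}: conflicting label for {fields[0]}")
            popmap[fields[0]] = fields[1]
    return popmap


def read_remap_table(path: str) -> dict[tuple[str, int], Optional[tuple[str, int]]]:
    """4-column TSV old_chrom, old_pos, new_chrom, new_pos ('-' = unmapped)."""
    table: dict[tuple[str, int], Optional[tuple[str, int]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise MalformedFileError(f"{path}:{lineno}: expected 4 columns")
            key = (fields[0], int(fields[1]))
            if fields[2] == "-" or fields[3] == "-":
                table[key] = None
            else:
                table[key] = (fields[2], int(fields[3]))
    return table


# ---------------------------------------------------------------------------
# FASTA / SAM helpers
# ---------------------------------------------------------------------------

def open_fasta(path: str) -> pysam.FastaFile:
    """Open an indexed FASTA, building the .fai on first use."""
    if not os.path.exists(str(path) + ".fai"):
        pysam.faidx(str(path))
    return pysam.FastaFile(str(path))


def ensure_indexed_bam(path: str, work_dir: Optional[str] = None) -> str:
    """Return a coordinate-sorted, indexed BAM for ``path``.

    Plain-text SAM cannot be randomly accessed, so SAM inputs are converted to
    sorted BAM (next to the input, or under ``work_dir``) and indexed.  BAM
    inputs are indexed in place if needed.
    """
    path = str(path)
    if path.endswith(".bam"):
        if not os.path.exists(path + ".bai"):
            pysam.index(path)
        return path
    if not path.endswith(".sam"):
        raise ValueError(f"expected .sam or .bam input, got {path}")
    base = os.path.basename(path)[:-4]
    out_dir = work_dir if work_dir is not None else os.path.dirname(os.path.abspath(path))
    bam = os.path.join(out_dir, base + ".sorted.bam")
    if not os.path.exists(bam) or os.path.getmtime(bam) < os.path.getmtime(path):
        pysam.sort("-o", bam, path)
        pysam.index(bam)
    elif not os.path.exists(bam + ".bai"):
        pysam.index(bam)
    return bam


def open_alignments(path: str, work_dir: Optional[str] = None) -> pysam.AlignmentFile:
    """Open SAM/BAM for random access (converting/indexing as needed)."""
    return pysam.AlignmentFile(ensure_indexed_bam(path, work_dir))


# ---------------------------------------------------------------------------
# Catalog VCF
# ---------------------------------------------------------------------------

#: INFO keys used by the catalog VCF serialization.
CATALOG_INFO_LINES = (
    '##INFO=<ID=RRA_CLASS,Number=1,Type=String,Description="RRA class (A/B/C/U)">',
    '##INFO=<ID=RRA_AF,Number=1,Type=Float,Description="Reference allele frequency in the panel">',
    '##INFO=<ID=RRA_COUNTS,Number=4,Type=Integer,Description="hom-ref,het,hom-alt,missing genotype counts">',
    '##INFO=<ID=RRA_POPS,Number=.,Type=String,Description="Populations carrying the reference allele">',
    '##INFO=<ID=RRA_TYPE,Number=1,Type=String,Description="Variant type (SNV/INS/DEL)">',
)


def build_vcf_header(
    contigs: Sequence[tuple[str, int]],
    info_lines: Sequence[str] = (),
    format_lines: Sequence[str] = (),
    samples: Sequence[str] = (),
    meta_lines: Sequence[str] = (),
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for line in meta_lines:
        header.add_line(line)
    for name, length in contigs:
        header.add_line(f"##contig=<ID={name},length={length}>")
    for line in info_lines:
        header.add_line(line)
    for line in format_lines:
        header.add_line(line)
    for sample in samples:
        header.add_sample(sample)
    return header
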