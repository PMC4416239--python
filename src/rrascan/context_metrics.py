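"""GC content and mappability of the sequence context around catalog loci.

Sequencing artifacts concentrate in GC-extreme and repetitive regions, so a
catalog of putative rare-reference-allele loci is screened by computing the
GC fraction and mean mappability of the 100-bp window centered on each locus
and comparing the distributions against windows sampled uniformly at random
from the same genome.  Windows are 0-based half-open; the locus anchor base
sits at the window center (left-biased for even sizes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .io_formats import BedGraphTrack, GenomicInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowMetrics:
    chrom: str
    window_start: int
    window_end: int
    gc_fraction: Optional[float]
    mean_mappability: Optional[float]
    clamped: bool = False


def window_around(
    chrom: str,
    pos: int,
    contig_length: int,
    size: int = 100,
) -> tuple[GenomicInterval, bool]:
    """Size-`size` window centered on a 1-based locus position.

    The anchor base (0-based ``pos - 1``) is placed at index ``size // 2``
    of the window, so even sizes are left-biased.  Windows truncated at a
    contig edge are clamped and flagged.
    """
    if not 1 <= pos <= contig_length:
        raise ValueError(f"position {pos} outside contig of length {contig_length}")
    center = pos - 1
    start = center - size // 2
    end = start + size
    clamped = start < 0 or end > contig_length
    return GenomicInterval(chrom, max(start, 0), min(end, contig_length)), clamped


def gc_content(sequence: str) -> Optional[float]:
    """(G+C) / (A+C+G+T), case-insensitive; None if no non-N bases."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        return None
    return gc / denom


def mean_mappability(track: BedGraphTrack, interval: GenomicInterval) -> float:
    """Arithmetic mean of per-base track scores over the interval.

    Bases absent from the track contribute 0 (with a logged warning), so a
    completely uncovered window scores 0.
    """
    if len(interval) == 0:
        raise ValueError("empty interval")
    values = track.values(interval)
    n_absent = sum(1 for v in values if v is None)
    if n_absent:
        logger.warning(
            "mean_mappability: %d/%d bases of %s:%d-%d absent from track (count as 0)",
            n_absent, len(values), interval.chrom, interval.start, interval.end,
        )
    return sum(v for v in values if v is not None) / len(values)


def sample_background(
    reference_fasta: pysam.FastaFile,
    n: int,
    size: int = 100,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Sample ``n`` non-clamped windows uniformly over valid start positions."""
    if n <= 0:
        raise ValueError("n must be positive")
    contigs = list(reference_fasta.references)
    starts_per_contig = [
        max(0, reference_fasta.get_reference_length(c) - size + 1) for c in contigs
    ]
    total = sum(starts_per_contig)
    if total == 0:
        raise ValueError(f"no contig can hold a window of size {size}")
    cumulative = np.cumsum(starts_per_contig)
    rng = np.random.default_rng(seed)
    draws = np.sort(rng.integers(0, total, size=n))
    intervals = []
    for d in draws:
        idx = int(np.searchsorted(cumulative, d, side="right"))
        offset = int(d - (cumulative[idx - 1] if idx else 0))
        intervals.append(GenomicInterval(contigs[idx], offset, offset + size))
    return intervals


def catalog_window_metrics(
    loci: Sequence,
    reference_fasta: pysam.FastaFile,
    mappability: Optional[BedGraphTrack] = None,
    size: int = 100,
) -> pd.DataFrame:
    """Per-locus window GC and mean mappability for a catalog."""
    rows = []
    for locus in loci:
        if locus.chrom not in reference_fasta.references:
            raise KeyError(f"contig {locus.chrom!r} absent from FASTA")
        interval, clamped = window_around(
            locus.chrom, locus.pos, reference_fasta.get_reference_length(locus.chrom), size
        )
        seq = reference_fasta.fetch(interval.chrom, interval.start, interval.end)
        rows.append(
            {
                "chrom": locus.chrom,
                "pos": locus.pos,
                "rra_class": locus.rra_class,
                "window_start": interval.start,
                "window_end": interval.end,
                "clamped": clamped,
                "gc_fraction": gc_content(seq),
                "mean_mappability": (
                    mean_mappability(mappability, interval) if mappability is not None else None
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "rra_class", "window_start", "window_end",
                 "clamped", "gc_fraction", "mean_mappability"],
    )


def background_window_metrics(
    reference_fasta: pysam.FastaFile,
    n: int,
    mappability: Optional[BedGraphTrack] = None,
    size: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """GC/mappability of ``n`` randomly sampled background windows."""
    rows = []
    for interval in sample_background(reference_fasta, n, size, seed):
        seq = reference_fasta.fetch(interval.chrom, interval.start, interval.end)
        rows.append(
            {
                "chrom": interval.chrom,
                "window_start": interval.start,
                "window_end": interval.end,
                "gc_fraction": gc_content(seq),
                "mean_mappability": (
                    mean_mappability(mappability, interval) if mappability is not None else None
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "window_start", "window_end", "gc_fraction", "mean_mappability"],
    )
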