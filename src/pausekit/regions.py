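"""Genomic intervals, gene models, and the strand-aware windows used by every
downstream density statistic.

Coordinate convention: 0-based, half-open ``[start, end)`` throughout, the BED
convention. On the minus strand the transcription start site (TSS) is the
interval's ``end`` coordinate (the first transcribed base is ``end - 1``), so
window arithmetic mirrors cleanly under strand reversal.

The three windows of interest:

* TSSR — the pausing-index numerator window, 50 bp upstream to 300 bp
  downstream of the TSS.
* gene body — the pausing-index denominator window, from 300 bp downstream of
  the TSS to 3 kb past the transcription end site (TES).
* promoter — TSS ± 1 kb, used for occupancy/expression correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import DataError

VALID_STRANDS = ("+", "-", ".")

# TSSR window: 50 bp upstream through 300 bp downstream of the TSS.
TSSR_UPSTREAM = 50
TSSR_DOWNSTREAM = 300
# Gene body: from TSS + BODY_START_OFFSET to TES + BODY_END_PAST_TES (sense direction).
BODY_START_OFFSET = 300
BODY_END_PAST_TES = 3000
DEFAULT_PROMOTER_FLANK = 1000
DEFAULT_ASSIGNMENT_WINDOW = 50_000


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise DataError(f"invalid strand {self.strand!r} (expected one of {VALID_STRANDS})")
        if self.start < 0 or self.start >= self.end:
            raise DataError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Length in bp of the overlap with *other* (0 if disjoint or on another chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """One canonical transcript model per gene with strand-aware TSS/TES."""

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise DataError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tes(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class PeakGeneAssignment:
    """A peak's nearest-TSS gene assignment within a distance window.

    ``distance_to_tss`` is signed in the gene's transcriptional orientation:
    positive values lie downstream of the TSS. ``is_promoter_1kb`` records
    whether the peak midpoint lies within 1 kb of *any* TSS, regardless of
    which gene (if any) it was assigned to.
    """

    peak: GenomicInterval
    gene_id: str | None
    distance_to_tss: int | None
    is_promoter_1kb: bool


def _clip_window(chrom: str, start: int, end: int, strand: str,
                 chrom_sizes: Mapping[str, int] | None) -> GenomicInterval:
    start = max(0, start)
    if chrom_sizes is not None and chrom in chrom_sizes:
        end = min(end, chrom_sizes[chrom])
    if end <= start:
        raise DataError(f"window on {chrom} collapsed to nothing after clipping")
    return GenomicInterval(chrom, start, end, strand)


def tssr_interval(gene: GeneModel,
                  chrom_sizes: Mapping[str, int] | None = None) -> GenomicInterval:
    """TSS region window: 50 bp upstream through 300 bp downstream of the TSS.

    350 bp unless clipped at the chromosome edge. This is the numerator window
    of the pausing index.
    """
    if gene.strand == "+":
        lo, hi = gene.tss - TSSR_UPSTREAM, gene.tss + TSSR_DOWNSTREAM
    else:
        lo, hi = gene.tss - TSSR_DOWNSTREAM, gene.tss + TSSR_UPSTREAM
    return _clip_window(gene.chrom, lo, hi, gene.strand, chrom_sizes)


def body_interval(gene: GeneModel,
                  chrom_sizes: Mapping[str, int] | None = None) -> GenomicInterval:
    """Gene body window: TSS + 300 bp through 3 kb past the TES (sense direction).

    Disjoint from :func:`tssr_interval` by construction; the denominator window
    of the pausing index.
    """
    if gene.strand == "+":
        lo, hi = gene.tss + BODY_START_OFFSET, gene.tes + BODY_END_PAST_TES
    else:
        lo, hi = gene.tes - BODY_END_PAST_TES, gene.tss - BODY_START_OFFSET
    return _clip_window(gene.chrom, lo, hi, gene.strand, chrom_sizes)


def promoter_interval(gene: GeneModel, flank: int = DEFAULT_PROMOTER_FLANK,
                      chrom_sizes: Mapping[str, int] | None = None) -> GenomicInterval:
    """Promoter window TSS ± *flank* bp (default 1 kb), clipped at 0."""
    if flank <= 0:
        raise DataError(f"promoter flank must be positive, got {flank}")
    return _clip_window(gene.chrom, gene.tss - flank, gene.tss + flank,
                        gene.strand, chrom_sizes)


def _signed_distance(midpoint: int, gene: GeneModel) -> int:
    d = midpoint - gene.tss
    return d if gene.strand == "+" else -d


def assign_peaks_to_genes(
    peaks: Sequence[GenomicInterval],
    genes: Iterable[GeneModel],
    window: int = DEFAULT_ASSIGNMENT_WINDOW,
    promoter_flank: int = DEFAULT_PROMOTER_FLANK,
) -> list[PeakGeneAssignment]:
    """Assign each peak to the gene whose TSS is nearest to the peak midpoint.

    A peak is assigned only when the nearest TSS is within *window* bp of its
    midpoint; equidistant candidates are broken lexicographically by gene_id so
    the result is deterministic. Each assignment also classifies the peak as
    promoter-proximal when its midpoint lies within *promoter_flank* of any TSS.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    out: list[PeakGeneAssignment] = []
    for peak in peaks:
        candidates = by_chrom.get(peak.chrom, [])
        mid = peak.midpoint
        best: GeneModel | None = None
        best_abs: int | None = None
        for g in candidates:
            d = abs(mid - g.tss)
            if d > window:
                continue
            if best_abs is None or d < best_abs or (d == best_abs and g.gene_id < best.gene_id):
                best, best_abs = g, d
        near_tss = any(abs(mid - g.tss) <= promoter_flank for g in candidates)
        if best is None:
            out.append(PeakGeneAssignment(peak, None, None, near_tss))
        else:
            out.append(PeakGeneAssignment(peak, best.gene_id,
                                          _signed_distance(mid, best), near_tss))
    return out
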