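"""Per-base coverage tracks, library-normalized region densities, input
subtraction, and TSS-anchored signal matrices (tag heatmaps / aggregation
profiles).

Density convention throughout: reads-per-million per bp, i.e. the mean
per-base read coverage over a region, scaled by 1e6 / library size. Reads
contribute coverage over their full aligned interval (no 5'-end collapsing or
fragment extension); a ``count_mode`` knob records this choice and offers
5'-end counting for comparison with tag-based tools.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .regions import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)


class SignalTrack:
    """Dense per-base coverage for one sequencing experiment.

    Parameters
    ----------
    coverage:
        chromosome -> per-base coverage array (length = covered extent).
    library_size:
        total mapped reads in the library; the denominator of
        reads-per-million normalization.
    label:
        free-text experiment name carried into outputs.
    reads:
        optional per-chromosome (sorted starts, sorted ends) retained so raw
        read counts per region can be recovered from the track.
    """

    def __init__(self, coverage: Mapping[str, np.ndarray], library_size: int,
                 label: str = "",
                 reads: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None):
        if library_size <= 0:
            raise DataError(f"library_size must be positive, got {library_size}")
        self.coverage = {c: np.asarray(a) for c, a in coverage.items()}
        for chrom, arr in self.coverage.items():
            if arr.size and arr.min() < 0:
                raise DataError(f"negative coverage on {chrom}")
        self.library_size = int(library_size)
        self.label = label
        self.reads = dict(reads) if reads is not None else None

    def chrom_coverage(self, chrom: str) -> np.ndarray | None:
        return self.coverage.get(chrom)

    def region_sum(self, region: GenomicInterval) -> float:
        """Total per-base coverage over *region*; bases beyond the covered
        extent (or on unknown chromosomes) contribute zero."""
        arr = self.coverage.get(region.chrom)
        if arr is None:
            return 0.0
        lo = min(region.start, arr.size)
        hi = min(region.end, arr.size)
        return float(arr[lo:hi].sum())

    def count_reads(self, region: GenomicInterval) -> int | None:
        """Number of retained reads overlapping *region* (None if reads were
        not kept)."""
        if self.reads is None:
            return None
        entry = self.reads.get(region.chrom)
        if entry is None:
            return 0
        starts, ends = entry
        # reads with start < region.end and end > region.start
        return int(np.searchsorted(starts, region.end, side="left")
                   - np.searchsorted(ends, region.start, side="right"))


@dataclass(frozen=True)
class RegionDensity:
    """Library- and length-normalized signal over one region."""

    region: GenomicInterval
    density: float  # reads-per-million per bp
    raw_reads: int | None = None


@dataclass(frozen=True)
class NetDensity:
    """Input-subtracted density with a validity flag (net <= 0 is unusable
    downstream, where it would make ratio statistics undefined)."""

    region: GenomicInterval
    net: float
    valid: bool


def _reads_to_arrays(reads) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Normalize read input (DataFrame, interval iterable, or path) to
    per-chromosome sorted start/end arrays."""
    if isinstance(reads, str):
        from .io import read_bed_intervals
        reads = read_bed_intervals(reads)
    if isinstance(reads, pd.DataFrame):
        groups = {}
        for chrom, sub in reads.groupby("chrom", sort=True):
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            if np.any(starts >= ends):
                bad = int(np.flatnonzero(starts >= ends)[0])
                raise DataError(
                    f"read with start >= end on {chrom}: "
                    f"[{starts[bad]}, {ends[bad]})")
            groups[str(chrom)] = (starts, ends)
    else:
        tmp: dict[str, tuple[list, list]] = {}
        for iv in reads:
            s, e = tmp.setdefault(iv.chrom, ([], []))
            s.append(iv.start)
            e.append(iv.end)
        groups = {c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
                  for c, (s, e) in tmp.items()}
    return groups


def coverage_from_reads(reads, library_size: int | None = None, label: str = "",
                        count_mode: str = "coverage",
                        chrom_sizes: Mapping[str, int] | None = None) -> SignalTrack:
    """Build a :class:`SignalTrack` from aligned-read intervals.

    *reads* may be a BED path, an iterable of :class:`GenomicInterval`, or a
    DataFrame with chrom/start/end columns. ``count_mode='coverage'`` adds 1
    over each read's full interval; ``'five-prime'`` adds 1 at the read start
    only. *library_size* defaults to the number of read records.
    """
    if count_mode not in ("coverage", "five-prime"):
        raise DataError(f"unknown count_mode {count_mode!r}")
    groups = _reads_to_arrays(reads)
    n_reads = sum(len(s) for s, _ in groups.values())
    if library_size is None:
        library_size = n_reads
    cov: dict[str, np.ndarray] = {}
    kept: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, (starts, ends) in groups.items():
        size = int(ends.max()) if len(ends) else 0
        if chrom_sizes is not None and chrom in chrom_sizes:
            size = max(size, chrom_sizes[chrom])
        diff = np.zeros(size + 1, dtype=np.int64)
        if count_mode == "coverage":
            np.add.at(diff, starts, 1)
            np.add.at(diff, ends, -1)
        else:
            np.add.at(diff, starts, 1)
            np.add.at(diff, np.minimum(starts + 1, size), -1)
        cov[chrom] = np.cumsum(diff[:-1])
        kept[chrom] = (np.sort(starts), np.sort(ends))
    if chrom_sizes is not None:
        for chrom, size in chrom_sizes.items():
            if chrom not in cov:
                cov[chrom] = np.zeros(size, dtype=np.int64)
                kept[chrom] = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    return SignalTrack(cov, library_size=library_size, label=label, reads=kept)


def track_from_bedgraph(path: str, library_size: int, label: str = "") -> SignalTrack:
    """Accept pre-computed bedGraph coverage with a user-supplied library size."""
    from .io import read_bedgraph
    return SignalTrack(read_bedgraph(path), library_size=library_size, label=label)


def region_density(track: SignalTrack, region: GenomicInterval) -> RegionDensity:
    """Mean per-base coverage over *region*, scaled to reads-per-million per bp."""
    if region.length <= 0:
        raise DataError("region length must be positive")
    if region.chrom not in track.coverage:
        warnings.warn(f"region chromosome {region.chrom!r} not covered by track "
                      f"{track.label!r}; density set to 0", stacklevel=2)
        return RegionDensity(region, 0.0, 0 if track.reads is not None else None)
    mean_cov = track.region_sum(region) / region.length
    return RegionDensity(region, mean_cov * 1e6 / track.library_size,
                         track.count_reads(region))


def net_density(signal: RegionDensity, input_: RegionDensity) -> NetDensity:
    """Input subtraction: signal density minus matched-input density over the
    identical region. Net <= 0 is flagged invalid (ChIP signal at or below
    background cannot support a ratio statistic)."""
    if signal.region != input_.region:
        raise DataError(
            f"net_density requires identical regions, got "
            f"{signal.region.chrom}:{signal.region.start}-{signal.region.end} vs "
            f"{input_.region.chrom}:{input_.region.start}-{input_.region.end}")
    net = signal.density - input_.density
    return NetDensity(signal.region, net, net > 0)


@dataclass
class SignalMatrixResult:
    """Binned signal matrix around anchors, plus its column-mean profile."""

    matrix: np.ndarray          # rows x bins, reads-per-million per bp
    row_ids: list[str]          # reference labels in row order
    profile: np.ndarray         # column means (the aggregation plot)
    bin_centers: np.ndarray     # bp offsets of bin centers relative to anchor

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.row_ids,
                            columns=[f"{int(c)}" for c in self.bin_centers])


def _anchor_of(ref) -> tuple[str, int, str, str]:
    """Return (chrom, anchor bp, strand, label) for a gene (TSS) or interval
    (midpoint)."""
    if isinstance(ref, GeneModel):
        return ref.chrom, ref.tss, ref.strand, ref.gene_id
    return ref.chrom, ref.midpoint, ref.strand, f"{ref.chrom}:{ref.start}-{ref.end}"


def signal_matrix(track: SignalTrack,
                  references: Sequence[GeneModel | GenomicInterval],
                  window: int = 2000, bin_size: int = 25,
                  order_by: Sequence[float] | None = None) -> SignalMatrixResult:
    """Tag heatmap: binned, library-normalized coverage around each reference.

    Rows are references, strand-oriented so downstream is rightward; columns
    span ±*window* about the anchor (TSS for genes, midpoint for intervals) in
    *bin_size* bins. When *order_by* is given, rows are sorted by it in
    descending order (e.g. by binding strength). The column-mean vector is the
    aggregation profile.
    """
    if len(references) == 0:
        raise DataError("signal_matrix needs at least one reference")
    if window % bin_size != 0:
        raise DataError(f"window ({window}) must be divisible by bin ({bin_size})")
    if order_by is not None and len(order_by) != len(references):
        raise DataError("order_by must align with references")
    nbins = 2 * window // bin_size
    scale = 1e6 / track.library_size
    rows = np.zeros((len(references), nbins))
    labels = []
    for i, ref in enumerate(references):
        chrom, anchor, strand, label = _anchor_of(ref)
        labels.append(label)
        arr = track.coverage.get(chrom)
        win = np.zeros(2 * window)
        if arr is not None:
            lo, hi = anchor - window, anchor + window
            src_lo, src_hi = max(lo, 0), max(min(hi, arr.size), 0)
            if src_hi > src_lo:
                win[src_lo - lo: src_hi - lo] = arr[src_lo:src_hi]
        if strand == "-":
            win = win[::-1]
        rows[i] = win.reshape(nbins, bin_size).mean(axis=1) * scale
    order = np.arange(len(references))
    if order_by is not None:
        order = np.argsort(-np.asarray(order_by, dtype=float), kind="stable")
    centers = np.arange(nbins) * bin_size - window + bin_size / 2
    matrix = rows[order]
    return SignalMatrixResult(matrix, [labels[i] for i in order],
                              matrix.mean(axis=0), centers)
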