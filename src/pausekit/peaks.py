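"""Exclusive set-intersection counts across peak families and gene sets
(UpSet-style summaries for binding time courses).

Peak "sharing" is evaluated on the merged-union scaffold: all peaks from all
timepoints are merged into non-overlapping regions, and each merged region is
tagged with the timepoints whose peak sets overlap it by at least
``min_overlap`` bp. Exclusive combination counts therefore always partition
the merged union.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain

import numpy as np
import pandas as pd

from .errors import DataError
from .regions import GenomicInterval


def merge_intervals(intervals) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals per chromosome (strand ignored)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


@dataclass
class IntersectionResult:
    """Exclusive intersection counts over a family of region or id sets."""

    counts: dict[frozenset, int]     # label combination -> count (only nonzero)
    union_size: int                  # merged-union regions (or union of ids)
    per_set_raw: dict[str, int]      # input cardinality per label (raw peaks / ids)
    per_set_merged: dict[str, int]   # merged regions hit per label

    def count(self, *labels) -> int:
        return self.counts.get(frozenset(labels), 0)

    def to_frame(self) -> pd.DataFrame:
        labels = sorted(self.per_set_raw)
        rows = []
        for combo, n in sorted(self.counts.items(),
                               key=lambda kv: (-kv[1], sorted(kv[0]))):
            rows.append({**{lab: int(lab in combo) for lab in labels}, "count": n})
        return pd.DataFrame(rows)


def _overlap_bp(region: GenomicInterval, starts: np.ndarray, ends: np.ndarray) -> int:
    """Max single-interval overlap of *region* with sorted intervals."""
    if starts.size == 0:
        return 0
    ov = np.minimum(ends, region.end) - np.maximum(starts, region.start)
    return int(ov.max()) if ov.size else 0


def peak_set_intersections(family: dict[str, list[GenomicInterval]],
                           min_overlap: int = 1) -> IntersectionResult:
    """Tag every merged-union region with the peak sets overlapping it by
    >= *min_overlap* bp and count exclusive label combinations.

    The counts partition the merged union: every merged region falls in
    exactly one combination cell.
    """
    if len(family) < 2:
        raise DataError("peak_set_intersections needs >= 2 peak sets")
    union = merge_intervals(chain.from_iterable(family.values()))
    indexed: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for label, peaks in family.items():
        per_chrom: dict[str, tuple[list, list]] = {}
        for iv in merge_intervals(peaks):
            s, e = per_chrom.setdefault(iv.chrom, ([], []))
            s.append(iv.start)
            e.append(iv.end)
        indexed[label] = {c: (np.asarray(s), np.asarray(e)) for c, (s, e) in per_chrom.items()}
    counts: dict[frozenset, int] = {}
    hit_per_label = {label: 0 for label in family}
    for region in union:
        tags = []
        for label, by_chrom in indexed.items():
            starts, ends = by_chrom.get(region.chrom, (np.empty(0), np.empty(0)))
            if _overlap_bp(region, starts, ends) >= min_overlap:
                tags.append(label)
                hit_per_label[label] += 1
        combo = frozenset(tags)
        counts[combo] = counts.get(combo, 0) + 1
    return IntersectionResult(counts, len(union),
                              {lab: len(p) for lab, p in family.items()},
                              hit_per_label)


def gene_set_intersections(families: dict[str, set]) -> IntersectionResult:
    """Exclusive intersection counts over gene-id sets (standard set algebra)."""
    if len(families) < 2:
        raise DataError("gene_set_intersections needs >= 2 sets")
    universe = set().union(*families.values())
    counts: dict[frozenset, int] = {}
    for gene in universe:
        combo = frozenset(lab for lab, s in families.items() if gene in s)
        counts[combo] = counts.get(combo, 0) + 1
    return IntersectionResult(counts, len(universe),
                              {lab: len(s) for lab, s in families.items()},
                              {lab: len(s) for lab, s in families.items()})
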