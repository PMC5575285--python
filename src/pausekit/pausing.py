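"""Per-gene pausing index (PI) and distribution-shift comparisons.

The pausing index of a gene is the ratio of input-subtracted, length- and
library-normalized RNAPII ChIP-seq density in the TSS region (TSSR, -50 to
+300 bp around the TSS) to that in the gene body (+300 bp downstream of the
TSS to 3 kb past the TES). High PI means a large fraction of engaged RNAPII
sits paused near the promoter rather than elongating through the body.

A gene's PI is undefined (and the gene excluded from comparisons) when it is
not transcriptionally active, or when ChIP signal does not exceed input in
either window.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .coverage import SignalTrack, net_density, region_density
from .errors import DataError
from .regions import GeneModel, body_interval, tssr_interval

logger = logging.getLogger(__name__)

EXCLUDED_NONE = "none"
EXCLUDED_NOT_EXPRESSED = "not_expressed"
EXCLUDED_SIGNAL_BELOW_INPUT = "signal_below_input"

DEFAULT_EXPRESSED_MIN_FPKM = 1.0
# below this combined sample size the two-sample KS p-value is computed exactly
KS_EXACT_MAX_N = 25


@dataclass(frozen=True)
class PausingRecord:
    gene_id: str
    tssr_net: float
    body_net: float
    pi: float  # NaN when excluded
    excluded_reason: str = EXCLUDED_NONE

    @property
    def defined(self) -> bool:
        return self.excluded_reason == EXCLUDED_NONE


def pausing_index(rnapii: SignalTrack, input_track: SignalTrack, gene: GeneModel,
                  chrom_sizes: Mapping[str, int] | None = None) -> PausingRecord:
    """Compute one gene's pausing index from RNAPII ChIP and matched input.

    Both window densities are input-subtracted; if either net density is <= 0
    the gene is excluded with reason ``signal_below_input`` (PI would be
    non-positive or divide by zero).
    """
    tssr = tssr_interval(gene, chrom_sizes)
    body = body_interval(gene, chrom_sizes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # uncovered-chromosome warnings handled via exclusion
        tssr_net = net_density(region_density(rnapii, tssr), region_density(input_track, tssr))
        body_net = net_density(region_density(rnapii, body), region_density(input_track, body))
    if not (tssr_net.valid and body_net.valid):
        return PausingRecord(gene.gene_id, tssr_net.net, body_net.net,
                             math.nan, EXCLUDED_SIGNAL_BELOW_INPUT)
    return PausingRecord(gene.gene_id, tssr_net.net, body_net.net,
                         tssr_net.net / body_net.net)


def pi_table(rnapii: SignalTrack, input_track: SignalTrack,
             genes: Iterable[GeneModel],
             expression: Mapping[str, float] | None = None,
             expressed_min_fpkm: float = DEFAULT_EXPRESSED_MIN_FPKM,
             chrom_sizes: Mapping[str, int] | None = None) -> list[PausingRecord]:
    """Pausing records for a gene universe, restricted to transcriptionally
    active genes.

    *expression* maps gene_id to FPKM; genes missing from it, or below
    *expressed_min_fpkm*, are excluded with reason ``not_expressed``. Pass
    ``expression=None`` to treat all genes as expressed.
    """
    records = []
    for gene in genes:
        if expression is not None:
            fpkm = expression.get(gene.gene_id, 0.0)
            if fpkm < expressed_min_fpkm:
                records.append(PausingRecord(gene.gene_id, math.nan, math.nan,
                                             math.nan, EXCLUDED_NOT_EXPRESSED))
                continue
        records.append(pausing_index(rnapii, input_track, gene, chrom_sizes))
    if not any(r.defined for r in records):
        warnings.warn("no gene has a defined pausing index", stacklevel=2)
    return records


def defined_pi(records: Iterable[PausingRecord]) -> np.ndarray:
    """Extract the defined-PI values that distribution comparisons consume."""
    return np.array([r.pi for r in records if r.defined])


def write_pi_tsv(path: str, records: Sequence[PausingRecord]) -> None:
    import pandas as pd
    pd.DataFrame([{
        "gene_id": r.gene_id,
        "tssr_net": r.tssr_net,
        "body_net": r.body_net,
        "pi": r.pi,
        "excluded_reason": r.excluded_reason,
    } for r in records]).to_csv(path, sep="\t", index=False, na_rep="NA")


def ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF support points and heights for cumulative plots."""
    x = np.sort(np.asarray(values, dtype=float))
    return x, np.arange(1, x.size + 1) / x.size


@dataclass(frozen=True)
class KSResult:
    statistic: float
    pvalue: float
    ecdf_a: tuple[np.ndarray, np.ndarray]
    ecdf_b: tuple[np.ndarray, np.ndarray]
    shift: str  # 'lower' | 'higher' | 'none' — location of sample b relative to a
    method: str


def ks_compare(pi_a, pi_b) -> KSResult:
    """Two-sample Kolmogorov–Smirnov comparison of two PI (or any value)
    samples.

    Uses the exact two-sided p-value when the combined sample is small
    (< 25 values), the asymptotic approximation otherwise. KS is invariant to
    any strictly increasing transform of both samples, so comparing raw PI or
    log10(PI) gives identical results. The ``shift`` field reports whether
    sample b sits at lower or higher values than sample a (by median).
    """
    a = np.asarray(pi_a, dtype=float)
    b = np.asarray(pi_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise DataError("ks_compare needs >= 2 finite values per sample")
    method = "exact" if a.size + b.size < KS_EXACT_MAX_N else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    med_a, med_b = np.median(a), np.median(b)
    shift = "none" if med_a == med_b else ("lower" if med_b < med_a else "higher")
    return KSResult(float(res.statistic), float(res.pvalue),
                    ecdf(a), ecdf(b), shift, method)
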