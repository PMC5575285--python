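"""Promoter occupancy and its relationship to expression: per-gene promoter
signal tables, smoothed-spline trend curves with rank correlation, binned
fold-change regression, and rank-based shift tests for per-region signal
gain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

from .coverage import SignalTrack, region_density
from .errors import DataError
from .regions import GeneModel, promoter_interval

DEFAULT_FC_BIN_WIDTH = 0.2   # log2 units
DEFAULT_MIN_GENES_PER_BIN = 10
DEFAULT_FC_PSEUDOCOUNT = 0.1


@dataclass(frozen=True)
class PromoterSignalRecord:
    """Input-subtracted promoter (TSS ± 1 kb) density for one gene.

    The net signal is kept as-is when <= 0 (flagged, never floored), since
    flooring would distort genome-wide correlation estimates.
    """

    gene_id: str
    signal: float
    factor_label: str = ""
    timepoint: float = math.nan

    @property
    def nonpositive(self) -> bool:
        return self.signal <= 0


def promoter_signal_table(track: SignalTrack, input_track: SignalTrack,
                          genes, flank: int = 1000, factor_label: str = "",
                          timepoint: float = math.nan,
                          chrom_sizes=None) -> list[PromoterSignalRecord]:
    """Library-normalized, input-subtracted density over TSS ± *flank* per gene."""
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # genes off-track score 0 - input
        for gene in genes:
            prom = promoter_interval(gene, flank, chrom_sizes)
            net = (region_density(track, prom).density
                   - region_density(input_track, prom).density)
            out.append(PromoterSignalRecord(gene.gene_id, net, factor_label, timepoint))
    return out


@dataclass
class SplineTrendResult:
    grid: np.ndarray
    trend: np.ndarray
    spearman_rho: float
    spearman_p: float


def spline_trend(x, y, grid_size: int = 200) -> SplineTrendResult:
    """Smoothing-spline trend of y on x plus Spearman rank correlation.

    The smoothing parameter is chosen by generalized cross-validation, so no
    degrees of freedom are fixed by hand. Duplicate x values are averaged
    before fitting (the spline needs strictly increasing abscissae); the rank
    correlation is computed on the raw pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 10:
        raise DataError(f"spline_trend needs >= 10 finite pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise DataError("spline_trend: x has no spread")
    rho, p = stats.spearmanr(x, y)
    ux, inv = np.unique(x, return_inverse=True)
    uy = np.bincount(inv, weights=y) / np.bincount(inv)
    spline = make_smoothing_spline(ux, uy)
    grid = np.linspace(x.min(), x.max(), grid_size)
    return SplineTrendResult(grid, spline(grid), float(rho), float(p))


def log2_fold_change(after, before, pseudocount: float = DEFAULT_FC_PSEUDOCOUNT) -> np.ndarray:
    """log2((after + pc) / (before + pc)); the pseudocount guards zeros."""
    after = np.asarray(after, dtype=float)
    before = np.asarray(before, dtype=float)
    return np.log2((after + pseudocount) / (before + pseudocount))


@dataclass
class BinnedRegressionResult:
    """OLS fit through per-bin mean fold changes."""

    bins: pd.DataFrame          # columns: bin_left, mean_x, mean_y, n_genes
    slope: float
    intercept: float
    r: float                    # Pearson R over bin means
    pvalue: float


def binned_foldchange_regression(ets1_fc, expr_fc,
                                 bin_width: float = DEFAULT_FC_BIN_WIDTH,
                                 min_genes: int = DEFAULT_MIN_GENES_PER_BIN,
                                 ) -> BinnedRegressionResult:
    """Group genes into fixed-width bins of occupancy log2 fold change, then
    regress mean expression change on mean occupancy change across bins.

    Bins with fewer than *min_genes* genes are dropped; at least 3 bins must
    survive. Returns the per-bin means, the OLS slope/intercept, Pearson R
    over the bin means, and the regression p-value.
    """
    x = np.asarray(ets1_fc, dtype=float)
    y = np.asarray(expr_fc, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    idx = np.floor(x / bin_width).astype(int)
    df = pd.DataFrame({"bin": idx, "x": x, "y": y})
    g = df.groupby("bin").agg(mean_x=("x", "mean"), mean_y=("y", "mean"),
                              n_genes=("x", "size")).reset_index()
    g = g[g["n_genes"] >= min_genes].reset_index(drop=True)
    if len(g) < 3:
        raise DataError(f"only {len(g)} bins with >= {min_genes} genes; need >= 3")
    g["bin_left"] = g.pop("bin") * bin_width
    mx, my = g["mean_x"].to_numpy(), g["mean_y"].to_numpy()
    if np.ptp(my) == 0:  # flat response: slope and correlation are zero by convention
        return BinnedRegressionResult(g, 0.0, float(my[0]), 0.0, 1.0)
    res = stats.linregress(mx, my)
    return BinnedRegressionResult(g, float(res.slope), float(res.intercept),
                                  float(res.rvalue), float(res.pvalue))


@dataclass(frozen=True)
class BoxSummary:
    """Box-plot summary: median, quartiles, whiskers at median ± 1.5 x IQR."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float

    @classmethod
    def from_values(cls, values) -> "BoxSummary":
        v = np.asarray(values, dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        return cls(float(med), float(q1), float(q3),
                   float(med - 1.5 * iqr), float(med + 1.5 * iqr))


@dataclass
class RankShiftResult:
    statistic: float   # Mann-Whitney U (unpaired) or Wilcoxon W (paired)
    pvalue: float
    summary_a: BoxSummary
    summary_b: BoxSummary
    paired: bool


def rank_shift_test(values_t0, values_t, paired: bool = False) -> RankShiftResult:
    """Two-sided rank test for a genome-wide signal shift between two
    region-signal samples, with box-plot summaries of each.

    Unpaired (default) uses the Mann–Whitney U test; paired uses the Wilcoxon
    signed-rank test on matched regions. All-tied data yields p = 1 with a
    warning rather than an error.
    """
    a = np.asarray(values_t0, dtype=float)
    b = np.asarray(values_t, dtype=float)
    if a.size < 3 or b.size < 3:
        raise DataError("rank_shift_test needs >= 3 values per group")
    summary = (BoxSummary.from_values(a), BoxSummary.from_values(b))
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all values tied; shift test is uninformative (p = 1)",
                      stacklevel=2)
        stat = a.size * b.size / 2 if not paired else 0.0
        return RankShiftResult(float(stat), 1.0, *summary, paired)
    if paired:
        if a.size != b.size:
            raise DataError("paired test needs equal-length samples")
        res = stats.wilcoxon(a, b, alternative="two-sided")
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return RankShiftResult(float(res.statistic), float(res.pvalue), *summary, paired)
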