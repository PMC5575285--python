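"""ERCC spike-in-anchored expression normalization and transcriptional
amplification statistics.

A factor that amplifies transcription per cell (an "amplifier") is invisible
to depth-based normalization: if every transcript rises by the same factor g,
equalizing sequencing depth divides g back out. External spike-in RNAs added
per cell-equivalent break the degeneracy — their per-cell abundance is fixed,
so after sequencing they absorb the global depth artifact, and a loess fit of
the sample-vs-reference log-ratio (M) against average intensity (A) on the
spike-in rows, subtracted from all rows, restores per-cell-comparable
expression.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import DataError
from .pausing import KSResult, ks_compare

ERCC_ID_PATTERN = re.compile(r"^ERCC-\d{5}$")

STATE_RAW = "raw"
STATE_NORMALIZED = "spikein_normalized"

MIN_SPIKEINS = 20
DEFAULT_LOESS_SPAN = 0.6
DEFAULT_LOG_PSEUDOCOUNT = 0.01
DEFAULT_MIN_EXPR = 0.5


@dataclass
class ExpressionTable:
    """Gene x sample FPKM table with spike-in flags and a normalization state.

    ``values`` is indexed by transcript/gene id; ``is_spikein`` is a boolean
    Series on the same index; ``lengths`` (bp) is optional metadata. The state
    moves ``raw`` -> ``spikein_normalized`` exactly once, via
    :func:`loess_normalize_to_spikeins`.
    """

    values: pd.DataFrame
    is_spikein: pd.Series
    lengths: pd.Series | None = None
    state: str = STATE_RAW

    def __post_init__(self) -> None:
        if not self.is_spikein.index.equals(self.values.index):
            self.is_spikein = self.is_spikein.reindex(self.values.index, fill_value=False)
        if (self.values.to_numpy() < 0).any():
            raise DataError("FPKM values must be >= 0")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def genes(self) -> pd.DataFrame:
        return self.values[~self.is_spikein]

    def spikeins(self) -> pd.DataFrame:
        return self.values[self.is_spikein]

    @classmethod
    def from_tsv(cls, path: str, ercc_ids: list[str] | None = None,
                 state: str = STATE_RAW) -> "ExpressionTable":
        """Read a TSV with a gene_id column, optional is_spikein / length
        columns, and one column per sample. Spike-ins are flagged by the
        is_spikein column, an explicit id list, or the ERCC-xxxxx id pattern.
        """
        df = pd.read_csv(path, sep="\t")
        if "gene_id" not in df.columns:
            raise DataError(f"{path}: expression table needs a gene_id column")
        df = df.set_index("gene_id")
        if "is_spikein" in df.columns:
            spike = df.pop("is_spikein").astype(bool)
        elif ercc_ids is not None:
            spike = pd.Series(df.index.isin(ercc_ids), index=df.index)
        else:
            spike = pd.Series([bool(ERCC_ID_PATTERN.match(str(i))) for i in df.index],
                              index=df.index)
        lengths = df.pop("length") if "length" in df.columns else None
        return cls(df.astype(float), spike, lengths, state)

    def to_tsv(self, path: str) -> None:
        out = self.values.copy()
        out.insert(0, "is_spikein", self.is_spikein.astype(int))
        if self.lengths is not None:
            out.insert(0, "length", self.lengths)
        out.to_csv(path, sep="\t", index_label="gene_id")


def fpkm(counts, lengths, library_size: float) -> np.ndarray:
    """Fragments per kilobase of transcript per million mapped fragments:
    count / (length/1e3) / (library_size/1e6)."""
    if library_size <= 0:
        raise DataError(f"library_size must be positive, got {library_size}")
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if (lengths <= 0).any():
        raise DataError("transcript lengths must be positive")
    return counts / (lengths / 1e3) / (library_size / 1e6)


def _ma(sample: np.ndarray, ref: np.ndarray, pc: float) -> tuple[np.ndarray, np.ndarray]:
    m = np.log2((sample + pc) / (ref + pc))
    a = 0.5 * np.log2((sample + pc) * (ref + pc))
    return m, a


def loess_normalize_to_spikeins(table: ExpressionTable, reference_sample: str,
                                span: float = DEFAULT_LOESS_SPAN,
                                pseudocount: float = DEFAULT_LOG_PSEUDOCOUNT,
                                min_spikeins: int = MIN_SPIKEINS) -> ExpressionTable:
    """Renormalize every sample to the reference using a loess curve fitted on
    spike-in rows in MA space.

    For each non-reference sample, M = log2(sample/ref) and
    A = (log2(sample) + log2(ref))/2 are formed with a pseudocount; a
    degree-1 loess with the given span is fitted to (A, M) over spike-in rows
    only, and the fitted trend is subtracted from all rows' M. Outside the
    spike-in A range the boundary correction is held constant. Spike-in
    abundances are fixed per cell, so the subtracted trend is exactly the
    per-cell depth/intensity artifact.
    """
    if table.state != STATE_RAW:
        raise DataError(f"table already normalized (state={table.state!r})")
    if reference_sample not in table.values.columns:
        raise DataError(f"reference sample {reference_sample!r} not in table")
    spike_mask = table.is_spikein.to_numpy()
    usable = spike_mask & (table.values > 0).all(axis=1).to_numpy()
    if usable.sum() < min_spikeins:
        raise DataError(
            f"need >= {min_spikeins} spike-ins nonzero in all samples, "
            f"got {int(usable.sum())}")
    ref = table.values[reference_sample].to_numpy(dtype=float)
    out = table.values.copy()
    for sample in table.values.columns:
        if sample == reference_sample:
            continue
        vals = table.values[sample].to_numpy(dtype=float)
        m, a = _ma(vals, ref, pseudocount)
        fit = lowess(m[usable], a[usable], frac=span, return_sorted=True)
        fa, fm = fit[:, 0], fit[:, 1]
        gene_a = np.clip(a, fa[0], fa[-1])  # constant correction beyond spike-in A range
        if a.min() < fa[0] or a.max() > fa[-1]:
            warnings.warn(
                f"sample {sample!r}: A range of transcripts exceeds spike-in range; "
                "boundary correction held constant", stacklevel=2)
        m_hat = np.interp(gene_a, fa, fm)
        corrected = (ref + pseudocount) * np.exp2(m - m_hat) - pseudocount
        out[sample] = np.maximum(corrected, 0.0)
    return replace(table, values=out, state=STATE_NORMALIZED)


def fraction_upregulated(table: ExpressionTable, ctrl: str, treat: str,
                         min_expr: float = DEFAULT_MIN_EXPR,
                         include_spikeins: bool = False) -> float:
    """Proportion of expressed transcripts strictly higher in *treat* than in
    *ctrl* (per-cell scale; requires a spike-in-normalized table).

    Transcripts with max(ctrl, treat) below *min_expr* are dropped first.
    """
    if table.state != STATE_NORMALIZED:
        raise DataError("fraction_upregulated requires a spikein_normalized table")
    df = table.values if include_spikeins else table.genes()
    c = df[ctrl].to_numpy(dtype=float)
    t = df[treat].to_numpy(dtype=float)
    keep = np.maximum(c, t) >= min_expr
    if not keep.any():
        raise DataError(f"no transcript passes min_expr={min_expr}")
    return float(np.mean(t[keep] > c[keep]))


def expression_shift_test(table: ExpressionTable, ctrl: str, treat: str,
                          min_expr: float = DEFAULT_MIN_EXPR,
                          pseudocount: float = DEFAULT_LOG_PSEUDOCOUNT) -> KSResult:
    """Kolmogorov–Smirnov comparison of per-cell log2 expression between
    conditions (the cumulative-distribution shift readout)."""
    if table.state != STATE_NORMALIZED:
        raise DataError("expression_shift_test requires a spikein_normalized table")
    genes = table.genes()
    c = genes[ctrl].to_numpy(dtype=float)
    t = genes[treat].to_numpy(dtype=float)
    keep = np.maximum(c, t) >= min_expr
    return ks_compare(np.log2(c[keep] + pseudocount), np.log2(t[keep] + pseudocount))


def median_log2_ratio(table: ExpressionTable, ctrl: str, treat: str,
                      min_expr: float = DEFAULT_MIN_EXPR,
                      pseudocount: float = DEFAULT_LOG_PSEUDOCOUNT) -> float:
    """Median per-gene log2(treat/ctrl): the global amplification readout."""
    genes = table.genes()
    c = genes[ctrl].to_numpy(dtype=float)
    t = genes[treat].to_numpy(dtype=float)
    keep = np.maximum(c, t) >= min_expr
    if not keep.any():
        raise DataError(f"no gene passes min_expr={min_expr}")
    return float(np.median(np.log2((t[keep] + pseudocount) / (c[keep] + pseudocount))))
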