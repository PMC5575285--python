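"""Readers and writers for the plain-text formats the package exchanges:
BED (intervals, reads, peaks), BED12/GTF gene models, bedGraph coverage, and
TSV tables.

BED is read natively (0-based half-open); GTF (1-based inclusive) is converted
to the internal convention on load via gffutils. When several transcripts share
a gene_id, the longest one is kept as the canonical model.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParseError
from .regions import GeneModel, GenomicInterval, PeakGeneAssignment

_SKIP_PREFIXES = ("#", "track", "browser")


def _bed_lines(path: str):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def read_bed_intervals(path: str, min_fields: int = 3) -> list[GenomicInterval]:
    """Read a BED3+ file as a list of :class:`GenomicInterval`.

    Strand is taken from column 6 when present, else '.'.
    """
    out: list[GenomicInterval] = []
    for lineno, fields in _bed_lines(path):
        if len(fields) < min_fields:
            raise ParseError(f"expected >= {min_fields} fields, got {len(fields)}",
                             path=path, line=lineno)
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"non-integer coordinates: {exc}", path=path, line=lineno)
        strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
        try:
            out.append(GenomicInterval(fields[0], start, end, strand))
        except DataError as exc:
            raise ParseError(str(exc), path=path, line=lineno)
    return out


def read_bed_genes(path: str) -> list[GeneModel]:
    """Read gene models from BED6/BED12 (name = gene_id, strand required).

    Multiple records sharing a gene_id are collapsed to the longest (canonical
    transcript selection).
    """
    best: dict[str, GeneModel] = {}
    n = 0
    for lineno, fields in _bed_lines(path):
        if len(fields) < 6:
            raise ParseError(f"gene BED needs >= 6 fields, got {len(fields)}",
                             path=path, line=lineno)
        name, strand = fields[3], fields[5]
        if strand not in ("+", "-"):
            raise ParseError(f"gene record needs explicit strand, got {strand!r}",
                             path=path, line=lineno)
        try:
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
        except (ValueError, DataError) as exc:
            raise ParseError(str(exc), path=path, line=lineno)
        n += 1
        model = GeneModel(name, iv)
        prev = best.get(name)
        if prev is None or model.length > prev.length:
            best[name] = model
    if n == 0:
        raise DataError(f"{path}: no gene records found")
    return sorted(best.values(), key=lambda g: (g.chrom, g.interval.start, g.gene_id))


def read_gtf_genes(path: str) -> list[GeneModel]:
    """Read gene models from GTF, converting to 0-based half-open coordinates.

    Transcript spans are taken from ``transcript`` features when present,
    otherwise reconstructed from exons; the longest transcript per gene_id is
    kept.
    """
    import gffutils

    try:
        db = gffutils.create_db(path, ":memory:", force=True, keep_order=True,
                                disable_infer_genes=True, disable_infer_transcripts=True)
    except Exception as exc:  # gffutils raises assorted types for malformed input
        raise ParseError(f"GTF parse failed: {exc}", path=path)

    spans: dict[str, dict[str, list]] = {}  # gene_id -> transcript_id -> [chrom, start, end, strand]
    featuretypes = set(db.featuretypes())
    use = "transcript" if "transcript" in featuretypes else ("mRNA" if "mRNA" in featuretypes else "exon")
    for feat in db.features_of_type(use):
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        tx_id = feat.attributes.get("transcript_id", [feat.id])[0]
        start0 = feat.start - 1  # GTF is 1-based inclusive
        rec = spans.setdefault(gene_id, {}).setdefault(tx_id, [feat.seqid, start0, feat.end, feat.strand])
        rec[1] = min(rec[1], start0)
        rec[2] = max(rec[2], feat.end)
    if not spans:
        raise DataError(f"{path}: no gene records found")
    models = []
    for gene_id, txs in spans.items():
        chrom, start, end, strand = max(txs.values(), key=lambda r: r[2] - r[1])
        if strand not in ("+", "-"):
            raise DataError(f"{path}: gene {gene_id} lacks a usable strand")
        models.append(GeneModel(gene_id, GenomicInterval(chrom, start, end, strand)))
    return sorted(models, key=lambda g: (g.chrom, g.interval.start, g.gene_id))


def load_gene_models(path: str, fmt: str | None = None) -> list[GeneModel]:
    """Load gene models from BED or GTF, inferring the format from the extension."""
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = "gtf" if ext in (".gtf", ".gff", ".gff3") else "bed"
    fmt = fmt.lower()
    if fmt in ("bed", "bed6", "bed12"):
        return read_bed_genes(path)
    if fmt in ("gtf", "gff"):
        return read_gtf_genes(path)
    raise DataError(f"unknown annotation format {fmt!r}")


def write_bed_intervals(path: str, intervals: Iterable[GenomicInterval],
                        names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def write_bed12_genes(path: str, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            s, e = g.interval.start, g.interval.end
            fh.write("\t".join(map(str, [
                g.chrom, s, e, g.gene_id, 0, g.strand,
                s, e, "0,0,0", 1, e - s, 0,
            ])) + "\n")


def write_reads_bed(path: str, reads: pd.DataFrame) -> None:
    """Write a reads table with columns chrom/start/end as BED3."""
    reads[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str) -> dict[str, np.ndarray]:
    """Read bedGraph into dense per-base coverage arrays keyed by chromosome."""
    cov: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, fields in _bed_lines(path):
        if len(fields) < 4:
            raise ParseError(f"bedGraph needs 4 fields, got {len(fields)}",
                             path=path, line=lineno)
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise ParseError(str(exc), path=path, line=lineno)
        cov.setdefault(fields[0], []).append((start, end, value))
    out = {}
    for chrom, runs in cov.items():
        size = max(e for _, e, _ in runs)
        arr = np.zeros(size, dtype=float)
        for s, e, v in runs:
            arr[s:e] = v
        out[chrom] = arr
    return out


def write_bedgraph(path: str, coverage: Mapping[str, np.ndarray]) -> None:
    """Write per-base coverage as run-length-encoded bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(coverage):
            arr = np.asarray(coverage[chrom])
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def write_assignments_tsv(path: str, assignments: Iterable[PeakGeneAssignment]) -> None:
    rows = [{
        "peak_chrom": a.peak.chrom,
        "peak_start": a.peak.start,
        "peak_end": a.peak.end,
        "gene_id": a.gene_id if a.gene_id is not None else "NA",
        "distance_to_tss": a.distance_to_tss if a.distance_to_tss is not None else "NA",
        "is_promoter_1kb": int(a.is_promoter_1kb),
    } for a in assignments]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
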