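"""Synthetic data with known ground truth for every stage of the analysis.

The generator emulates three data-generating processes:

* RNAPII ChIP-seq as a two-compartment process: each gene receives
  promoter-proximal (TSSR) reads at rate ``alpha * depth`` and gene-body reads
  at rate ``alpha * r * depth * L2/L1``, where ``r`` is the pause-release
  probability. After length normalization the expected TSSR/body density
  ratio — the quantity the pausing index estimates — is exactly ``1/r``.
  Pause release is modeled at the density level, not via polymerase kinetics;
  that is sufficient to exercise the estimator.
* Promoter ChIP (an ETS1-like factor) whose promoter read intensity grows
  with log(1 + mu_g), so occupancy–expression correlation is positive with a
  tunable noise level.
* Spike-in RNA-seq: per-cell transcript counts are negative binomial with a
  global amplification factor g applied to the treatment sample, while 92
  ERCC-like spike-ins keep fixed per-cell abundance. Both samples are then
  rescaled to equal sequencing depth, so naive depth normalization hides g
  and only spike-in anchoring can recover it.

Reads are emitted only for the chromosomes that carry genes; the rest of the
mappable genome (``genome_size``) contributes background reads to the library
size analytically, exactly as reads mapping outside the regions of interest
would in a real library. Library sizes are therefore reported alongside the
read sets and must be passed to coverage construction.

All outputs are deterministic functions of (config, seed): each stage draws
from an independent child generator of the config seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .coverage import SignalTrack, coverage_from_reads
from .errors import ConfigError
from .regions import (BODY_END_PAST_TES, BODY_START_OFFSET, GeneModel,
                      GenomicInterval, body_interval, promoter_interval,
                      tssr_interval)
from .spikein import ExpressionTable, fpkm

# child-generator stream ids, so each stage is independently reproducible
_STREAM_GENES = 0
_STREAM_RNAPII_CONTROL = 1
_STREAM_RNAPII_TREATMENT = 2
_STREAM_PROMOTER_CHIP = 3
_STREAM_RNASEQ = 4


@dataclass
class SimulationConfig:
    """Tunable study conditions for the synthetic cohort.

    Defaults describe a modest endothelial-like experiment: a few hundred
    genes with log-normal lengths, half of them bound by the treatment factor,
    pause-release probability 0.25 (expected pausing index 4), a treatment
    that doubles release at bound genes, 1.3-fold global mRNA amplification,
    and an hg19-scale mappable genome so that input subtraction behaves as it
    does on real libraries.
    """

    seed: int
    n_genes: int = 500
    n_chroms: int = 2
    gene_length_meanlog: float = math.log(4000.0)
    gene_length_sdlog: float = 0.5
    min_gene_length: int = 1000
    min_gap: int = 10_000          # keeps TSSR/body windows of neighbors disjoint
    extra_gap_max: int = 5_000
    genome_size: float = 2.5e9     # total mappable genome contributing background
    # RNAPII model
    alpha_sdlog: float = 0.5       # per-gene initiation-rate spread (meanlog 0)
    release_prob: float = 0.25     # r; expected PI = 1/r
    bound_fraction: float = 0.5
    treatment_release_multiplier: float = 2.0  # applied to r at bound genes, capped at 1
    depth: float = 200.0           # expected TSSR reads per gene at alpha = 1
    background_per_bp: float = 0.008  # input/background read-start rate (reads per bp)
    read_length: int = 50
    # promoter ChIP model
    promoter_chip_scale: float = 30.0   # reads per log-intensity unit
    promoter_chip_noise_sd: float = 0.25
    # expression model
    mu_meanlog: float = math.log(100.0)   # per-cell abundance, arbitrary units
    mu_sdlog: float = 1.5
    rnaseq_depth: float = 3e7             # sequenced fragments per library
    dispersion: float = 0.05       # NB dispersion phi: var = mu + phi mu^2
    amplification: float = 1.3     # global per-cell mRNA factor g in treatment
    n_spikeins: int = 92
    spikein_decades: float = 4.0
    spikein_share: float = 0.03    # spike-in fraction of expected gene reads

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed: a seed is mandatory (no silent nondeterminism)")
        if not (0 < self.release_prob <= 1):
            raise ConfigError(f"release_prob: must be in (0, 1], got {self.release_prob}")
        for name in ("depth", "amplification", "promoter_chip_scale",
                     "genome_size", "mu_meanlog", "rnaseq_depth"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be positive")
        for name in ("background_per_bp", "dispersion", "promoter_chip_noise_sd",
                     "bound_fraction", "spikein_share"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0")
        if self.bound_fraction > 1:
            raise ConfigError("bound_fraction: must be <= 1")
        if self.min_gene_length <= BODY_START_OFFSET:
            raise ConfigError("min_gene_length: must exceed the body start offset")
        if self.n_spikeins < 1:
            raise ConfigError("n_spikeins: must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class SimulatedGenome:
    """Gene models plus the per-gene ground truth the tests recover."""

    genes: list[GeneModel]
    truth: pd.DataFrame      # one row per gene (see generate_genes)
    chrom_sizes: dict[str, int]
    config: SimulationConfig


def generate_genes(config: SimulationConfig) -> SimulatedGenome:
    """Place non-overlapping gene models with >= min_gap spacing on both
    strands, and draw the per-gene ground-truth parameters.

    Truth columns: gene_id, chrom, start, end, strand, length, alpha, bound,
    release_prob, release_prob_treatment, expected_pi (=1/r) for both
    conditions, and expression mean mu.
    """
    rng = config.rng(_STREAM_GENES)
    n = config.n_genes
    lengths = np.exp(rng.normal(config.gene_length_meanlog,
                                config.gene_length_sdlog, n))
    lengths = np.maximum(lengths.astype(np.int64), config.min_gene_length)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    gaps = config.min_gap + rng.integers(0, config.extra_gap_max + 1, n)
    alpha = np.exp(rng.normal(0.0, config.alpha_sdlog, n))
    bound = rng.random(n) < config.bound_fraction
    mu = np.exp(rng.normal(config.mu_meanlog, config.mu_sdlog, n))

    r_ctrl = np.full(n, config.release_prob)
    r_treat = np.where(bound,
                       np.minimum(1.0, r_ctrl * config.treatment_release_multiplier),
                       r_ctrl)

    per_chrom = int(math.ceil(n / config.n_chroms))
    genes: list[GeneModel] = []
    rows = []
    chrom_sizes: dict[str, int] = {}
    cursor, chrom_idx = None, 0
    for i in range(n):
        if i % per_chrom == 0:
            if cursor is not None:
                chrom_sizes[chrom] = cursor + config.min_gap
            chrom_idx = i // per_chrom + 1
            chrom = f"chrSim{chrom_idx}"
            cursor = config.min_gap
        start = cursor + int(gaps[i])
        end = start + int(lengths[i])
        gid = f"gene{i:05d}"
        genes.append(GeneModel(gid, GenomicInterval(chrom, start, end, str(strands[i]))))
        rows.append({
            "gene_id": gid, "chrom": chrom, "start": start, "end": end,
            "strand": str(strands[i]), "length": int(lengths[i]),
            "alpha": alpha[i], "bound": bool(bound[i]),
            "release_prob": r_ctrl[i], "release_prob_treatment": r_treat[i],
            "expected_pi_control": 1.0 / r_ctrl[i],
            "expected_pi_treatment": 1.0 / r_treat[i],
            "mu": mu[i],
        })
        cursor = end
    chrom_sizes[chrom] = cursor + config.min_gap
    genic = sum(chrom_sizes.values())
    if genic > config.genome_size:
        raise ConfigError(
            f"genome_size: genic extent {genic} exceeds genome_size "
            f"{config.genome_size:g}; too many/long genes for this genome")
    truth = pd.DataFrame(rows).set_index("gene_id", drop=False)
    return SimulatedGenome(genes, truth, chrom_sizes, config)


def _place_reads(rng: np.random.Generator, win_start: np.ndarray,
                 win_end: np.ndarray, counts: np.ndarray, chroms: np.ndarray,
                 read_length: int) -> pd.DataFrame:
    """Uniformly place `counts[i]` fully-contained reads in each window i."""
    rep_start = np.repeat(win_start, counts)
    rep_span = np.repeat(win_end - win_start - read_length + 1, counts)
    rep_chrom = np.repeat(chroms, counts)
    starts = rep_start + rng.integers(0, np.maximum(rep_span, 1))
    return pd.DataFrame({"chrom": rep_chrom, "start": starts,
                         "end": starts + read_length})


def _background_reads(rng: np.random.Generator, chrom_sizes: dict[str, int],
                      rate_per_bp: float, read_length: int,
                      genome_size: float) -> tuple[pd.DataFrame, int]:
    """Uniform background over the genome. Reads on gene-bearing chromosomes
    are materialized; the rest of the mappable genome contributes only a
    (Poisson-sampled) count to the library size."""
    frames = []
    genic = 0
    for chrom, size in sorted(chrom_sizes.items()):
        n = rng.poisson(rate_per_bp * size)
        genic += size
        if n:
            starts = rng.integers(0, max(size - read_length, 1), n)
            frames.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                        "end": starts + read_length}))
    offgene = int(rng.poisson(rate_per_bp * max(genome_size - genic, 0.0)))
    emitted = (pd.concat(frames, ignore_index=True) if frames
               else pd.DataFrame({"chrom": pd.Series(dtype=str),
                                  "start": pd.Series(dtype=np.int64),
                                  "end": pd.Series(dtype=np.int64)}))
    return emitted, emitted.shape[0] + offgene


def _sort_reads(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"],
                          kind="mergesort").reset_index(drop=True)


@dataclass
class ReadSet:
    """Reads on gene-bearing chromosomes plus the full library size."""

    reads: pd.DataFrame      # columns chrom, start, end
    library_size: int
    label: str

    def to_track(self, chrom_sizes: dict[str, int]) -> SignalTrack:
        return coverage_from_reads(self.reads, library_size=self.library_size,
                                   label=self.label, chrom_sizes=chrom_sizes)


def simulate_rnapii_experiment(sim: SimulatedGenome,
                               condition: str = "control") -> tuple[ReadSet, ReadSet]:
    """Simulate one RNAPII ChIP library plus its matched input.

    Per gene: Poisson(alpha * depth) reads uniform in the TSSR and
    Poisson(alpha * r * depth * L2/L1) reads uniform in the body, which fixes
    the expected density ratio at 1/r. Both ChIP and input receive uniform
    genome-wide background at ``background_per_bp``.
    """
    if condition not in ("control", "treatment"):
        raise ConfigError(f"condition: expected control|treatment, got {condition!r}")
    cfg = sim.config
    stream = _STREAM_RNAPII_CONTROL if condition == "control" else _STREAM_RNAPII_TREATMENT
    rng = cfg.rng(stream)

    r_col = "release_prob" if condition == "control" else "release_prob_treatment"
    alpha = sim.truth["alpha"].to_numpy()
    r = sim.truth[r_col].to_numpy()

    tssr = [tssr_interval(g, sim.chrom_sizes) for g in sim.genes]
    body = [body_interval(g, sim.chrom_sizes) for g in sim.genes]
    t_start = np.array([w.start for w in tssr])
    t_end = np.array([w.end for w in tssr])
    b_start = np.array([w.start for w in body])
    b_end = np.array([w.end for w in body])
    chroms = np.array([g.chrom for g in sim.genes])
    l1 = (t_end - t_start).astype(float)
    l2 = (b_end - b_start).astype(float)

    n_tssr = rng.poisson(alpha * cfg.depth)
    n_body = rng.poisson(alpha * r * cfg.depth * l2 / l1)
    frames = [
        _place_reads(rng, t_start, t_end, n_tssr, chroms, cfg.read_length),
        _place_reads(rng, b_start, b_end, n_body, chroms, cfg.read_length),
    ]
    chip_bg, chip_bg_total = _background_reads(rng, sim.chrom_sizes,
                                               cfg.background_per_bp,
                                               cfg.read_length, cfg.genome_size)
    chip = _sort_reads(pd.concat(frames + [chip_bg], ignore_index=True))
    chip_lib = int(n_tssr.sum() + n_body.sum() + chip_bg_total)

    input_bg, input_lib = _background_reads(rng, sim.chrom_sizes,
                                            cfg.background_per_bp,
                                            cfg.read_length, cfg.genome_size)
    return (ReadSet(chip, chip_lib, f"rnapii_{condition}"),
            ReadSet(_sort_reads(input_bg), max(input_lib, 1), f"input_{condition}"))


def simulate_promoter_chip(sim: SimulatedGenome) -> ReadSet:
    """Simulate a promoter-binding factor whose occupancy tracks expression.

    Per-gene promoter read intensity is ``scale * log(1 + mu_g)`` with
    log-normal noise of sd ``promoter_chip_noise_sd``; at noise 0 the counts
    are deterministic (rounded expectations), making the occupancy–expression
    rank correlation 1 up to count quantization.
    """
    cfg = sim.config
    rng = cfg.rng(_STREAM_PROMOTER_CHIP)
    mu = sim.truth["mu"].to_numpy()
    intensity = cfg.promoter_chip_scale * np.log1p(mu)
    if cfg.promoter_chip_noise_sd > 0:
        intensity = intensity * np.exp(rng.normal(0.0, cfg.promoter_chip_noise_sd,
                                                  mu.size))
        counts = rng.poisson(intensity)
    else:
        counts = np.rint(intensity).astype(np.int64)
    proms = [promoter_interval(g, chrom_sizes=sim.chrom_sizes) for g in sim.genes]
    reads = _place_reads(rng,
                         np.array([p.start for p in proms]),
                         np.array([p.end for p in proms]),
                         counts,
                         np.array([g.chrom for g in sim.genes]),
                         cfg.read_length)
    return ReadSet(_sort_reads(reads), max(int(counts.sum()), 1), "promoter_chip")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + phi mu^2; phi = 0 degenerates to the
    noiseless expectation (for closed-form checks)."""
    if dispersion == 0:
        return mean.astype(float)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(float)


def spikein_abundances(config: SimulationConfig,
                       total_gene_expression: float) -> np.ndarray:
    """Fixed spike-in abundances: log-uniform ladder over
    ``spikein_decades`` decades, scaled so spike-ins take ``spikein_share``
    of the expected gene reads (ERCC-like dynamic range)."""
    ladder = np.power(10.0, np.linspace(0.0, config.spikein_decades,
                                        config.n_spikeins))
    return ladder * (config.spikein_share * total_gene_expression / ladder.sum())


def simulate_spikein_rnaseq(sim: SimulatedGenome) -> ExpressionTable:
    """Simulate the control/treatment spike-in RNA-seq experiment.

    Gene counts are NB(mu, phi) in control and NB(g*mu, phi) in treatment;
    spike-in counts are Poisson around the same fixed abundances in both
    samples. Both samples are rescaled to identical sequencing depth before
    FPKM, so the global factor g is invisible to depth normalization and
    recoverable only through the spike-ins.
    """
    cfg = sim.config
    rng = cfg.rng(_STREAM_RNASEQ)
    mu = sim.truth["mu"].to_numpy()
    # per-cell abundances are scaled so the control library sequences
    # rnaseq_depth fragments in expectation
    s = cfg.rnaseq_depth / (mu.sum() * (1.0 + cfg.spikein_share))
    counts_c = _nb_counts(rng, s * mu, cfg.dispersion)
    counts_t = _nb_counts(rng, s * cfg.amplification * mu, cfg.dispersion)

    spike_mu = spikein_abundances(cfg, float(s * mu.sum()))
    if cfg.dispersion == 0:
        spikes_c = spike_mu.copy()
        spikes_t = spike_mu.copy()
    else:
        spikes_c = rng.poisson(spike_mu).astype(float)
        spikes_t = rng.poisson(spike_mu).astype(float)

    all_c = np.concatenate([counts_c, spikes_c])
    all_t = np.concatenate([counts_t, spikes_t])
    depth = all_c.sum()  # equalize sequencing depth to the control total
    all_t = all_t * (depth / all_t.sum())

    gene_lengths = sim.truth["length"].to_numpy(dtype=float)
    spike_lengths = np.rint(np.linspace(250, 2000, cfg.n_spikeins))
    lengths = np.concatenate([gene_lengths, spike_lengths])
    ids = list(sim.truth["gene_id"]) + [f"ERCC-{i:05d}" for i in range(cfg.n_spikeins)]
    values = pd.DataFrame({
        "control": fpkm(all_c, lengths, depth),
        "treatment": fpkm(all_t, lengths, depth),
    }, index=pd.Index(ids, name="gene_id"))
    is_spike = pd.Series([False] * cfg.n_genes + [True] * cfg.n_spikeins,
                         index=values.index)
    return ExpressionTable(values, is_spike,
                           pd.Series(lengths, index=values.index))
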