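"""End-to-end orchestration: simulate -> coverage/PI -> distribution
comparisons -> spike-in normalization -> report, with a reproducibility
manifest.

The YAML config has four optional sections::

    seed: 1                    # required (also settable per-section)
    simulate: {...}            # SimulationConfig overrides
    pausing:
      expressed_min_fpkm: 1.0
    spikein:
      reference: control
      span: 0.6
      min_expr: 0.5

Stages run in dependency order (simulate, pausing, expression, report); a
subset can be requested, in which case upstream outputs must already exist in
the output directory. Deterministic stages re-run from an identical config
produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, PausekitError
from .io import write_bed12_genes, write_reads_bed
from .pausing import defined_pi, ks_compare, pi_table, write_pi_tsv
from .simulate import (SimulationConfig, generate_genes,
                       simulate_rnapii_experiment, simulate_spikein_rnaseq)
from .spikein import (ExpressionTable, expression_shift_test,
                      fraction_upregulated, loess_normalize_to_spikeins,
                      median_log2_ratio)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "pausing", "expression", "report")

_PAUSING_KEYS = {"expressed_min_fpkm"}
_SPIKEIN_KEYS = {"reference", "span", "min_expr"}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run: config hash, seed, versions, and the
    checksummed outputs of every executed stage."""

    tool_version: str
    seed: int
    config_hash: str
    stages: dict[str, dict[str, str]] = field(default_factory=dict)

    def add_output(self, stage: str, path: str) -> None:
        self.stages.setdefault(stage, {})[os.path.basename(path)] = _sha256(path)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {"seed", "simulate", "pausing", "spikein"}
    for key in cfg:
        if key not in known:
            raise ConfigError(f"{key}: unknown config section")
    if "seed" not in cfg or not isinstance(cfg["seed"], int):
        raise ConfigError("seed: required integer")
    sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    for key in cfg.get("simulate") or {}:
        if key not in sim_fields:
            raise ConfigError(f"simulate.{key}: unknown field")
    for section, keys in (("pausing", _PAUSING_KEYS), ("spikein", _SPIKEIN_KEYS)):
        for key in cfg.get(section) or {}:
            if key not in keys:
                raise ConfigError(f"{section}.{key}: unknown field")
    return cfg


def _require(path: str, stage: str) -> str:
    if not os.path.exists(path):
        raise PausekitError(
            f"stage {stage!r}: missing upstream output {path!r} "
            "(run the earlier stages first)")
    return path


def run_pipeline(config_path: str, out_dir: str,
                 stages: tuple[str, ...] | None = None) -> RunManifest:
    """Execute the requested stages and write a manifest; returns it."""
    cfg = load_config(config_path)
    stages = tuple(stages) if stages else STAGES
    for s in stages:
        if s not in STAGES:
            raise ConfigError(f"unknown stage {s!r}; choose from {STAGES}")
    os.makedirs(out_dir, exist_ok=True)

    sim_cfg = SimulationConfig(seed=cfg["seed"], **(cfg.get("simulate") or {}))
    manifest = RunManifest(__version__, cfg["seed"], sim_cfg.config_hash())
    manifest.stages["inputs"] = {os.path.basename(config_path): _sha256(config_path)}
    p = lambda name: os.path.join(out_dir, name)

    sim = generate_genes(sim_cfg)  # cheap; downstream stages reuse it in-process

    if "simulate" in stages:
        logger.info("stage=simulate config=%s", sim_cfg.config_hash())
        write_bed12_genes(p("genes.bed12"), sim.genes)
        sim.truth.to_csv(p("truth.tsv"), sep="\t", index=False)
        libsizes = {}
        for cond in ("control", "treatment"):
            chip, inp = simulate_rnapii_experiment(sim, cond)
            write_reads_bed(p(f"rnapii_{cond}.bed"), chip.reads)
            write_reads_bed(p(f"input_{cond}.bed"), inp.reads)
            libsizes[f"rnapii_{cond}"] = chip.library_size
            libsizes[f"input_{cond}"] = inp.library_size
        with open(p("library_sizes.json"), "w") as fh:
            json.dump(libsizes, fh, indent=2, sort_keys=True)
        expr = simulate_spikein_rnaseq(sim)
        expr.to_tsv(p("expression_raw.tsv"))
        for name in ("genes.bed12", "truth.tsv", "library_sizes.json",
                     "expression_raw.tsv", "rnapii_control.bed", "input_control.bed",
                     "rnapii_treatment.bed", "input_treatment.bed"):
            manifest.add_output("simulate", p(name))

    if "pausing" in stages:
        logger.info("stage=pausing config=%s", sim_cfg.config_hash())
        for name in ("rnapii_control.bed", "input_control.bed",
                     "rnapii_treatment.bed", "input_treatment.bed",
                     "library_sizes.json", "expression_raw.tsv"):
            _require(p(name), "pausing")
        with open(p("library_sizes.json")) as fh:
            libsizes = json.load(fh)
        expr = ExpressionTable.from_tsv(p("expression_raw.tsv"))
        fpkm_by_gene = expr.genes()["control"].to_dict()
        min_fpkm = (cfg.get("pausing") or {}).get("expressed_min_fpkm", 1.0)
        pis = {}
        from .coverage import coverage_from_reads
        for cond in ("control", "treatment"):
            chip = coverage_from_reads(p(f"rnapii_{cond}.bed"),
                                       library_size=libsizes[f"rnapii_{cond}"],
                                       chrom_sizes=sim.chrom_sizes)
            inp = coverage_from_reads(p(f"input_{cond}.bed"),
                                      library_size=libsizes[f"input_{cond}"],
                                      chrom_sizes=sim.chrom_sizes)
            records = pi_table(chip, inp, sim.genes, fpkm_by_gene,
                               expressed_min_fpkm=min_fpkm,
                               chrom_sizes=sim.chrom_sizes)
            write_pi_tsv(p(f"pi_{cond}.tsv"), records)
            manifest.add_output("pausing", p(f"pi_{cond}.tsv"))
            pis[cond] = defined_pi(records)
        ks = ks_compare(pis["control"], pis["treatment"])
        with open(p("ks_pausing.json"), "w") as fh:
            json.dump({"statistic": ks.statistic, "pvalue": ks.pvalue,
                       "shift": ks.shift, "method": ks.method,
                       "n_control": int(pis["control"].size),
                       "n_treatment": int(pis["treatment"].size)},
                      fh, indent=2, sort_keys=True)
        manifest.add_output("pausing", p("ks_pausing.json"))

    if "expression" in stages:
        logger.info("stage=expression config=%s", sim_cfg.config_hash())
        _require(p("expression_raw.tsv"), "expression")
        sp = cfg.get("spikein") or {}
        table = ExpressionTable.from_tsv(p("expression_raw.tsv"))
        norm = loess_normalize_to_spikeins(table, sp.get("reference", "control"),
                                           span=sp.get("span", 0.6))
        norm.to_tsv(p("expression_normalized.tsv"))
        min_expr = sp.get("min_expr", 0.5)
        ref = sp.get("reference", "control")
        other = [c for c in norm.samples if c != ref][0]
        ks = expression_shift_test(norm, ref, other, min_expr=min_expr)
        summary = {
            "fraction_upregulated": fraction_upregulated(norm, ref, other,
                                                         min_expr=min_expr),
            "median_log2_ratio": median_log2_ratio(norm, ref, other,
                                                   min_expr=min_expr),
            "ks_statistic": ks.statistic, "ks_pvalue": ks.pvalue,
            "ks_shift": ks.shift,
        }
        with open(p("amplification.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        manifest.add_output("expression", p("expression_normalized.tsv"))
        manifest.add_output("expression", p("amplification.json"))

    if "report" in stages:
        for name in ("ks_pausing.json", "amplification.json"):
            _require(p(name), "report")
        with open(p("ks_pausing.json")) as fh:
            ksp = json.load(fh)
        with open(p("amplification.json")) as fh:
            amp = json.load(fh)
        lines = [
            f"pausekit {__version__} run report (config {sim_cfg.config_hash()}, "
            f"seed {cfg['seed']})",
            "",
            "Pausing-index shift (control vs treatment, defined PIs):",
            f"  KS D = {ksp['statistic']:.4f}, p = {ksp['pvalue']:.3g}, "
            f"treatment shifted {ksp['shift']} "
            f"(n = {ksp['n_control']}/{ksp['n_treatment']})",
            "",
            "Spike-in-anchored expression (per cell):",
            f"  fraction of expressed transcripts up in treatment = "
            f"{amp['fraction_upregulated']:.3f}",
            f"  median gene log2(treatment/control) = "
            f"{amp['median_log2_ratio']:.3f}",
            f"  KS D = {amp['ks_statistic']:.4f}, p = {amp['ks_pvalue']:.3g}, "
            f"shifted {amp['ks_shift']}",
            "",
        ]
        with open(p("report.txt"), "w") as fh:
            fh.write("\n".join(lines))
        manifest.add_output("report", p("report.txt"))

    manifest.to_json(p("manifest.json"))
    return manifest
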