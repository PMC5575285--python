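"""Ground-truth recovery and determinism of the synthetic-data generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pausekit import (ConfigError, SimulationConfig, defined_pi,
                      generate_genes, pi_table, promoter_signal_table,
                      simulate_promoter_chip, simulate_rnapii_experiment,
                      simulate_spikein_rnaseq)
from pausekit.io import write_bed12_genes
from pausekit.regions import body_interval, promoter_interval, tssr_interval


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigError, match="release_prob"):
            SimulationConfig(seed=1, release_prob=0.0)
        with pytest.raises(ConfigError, match="depth"):
            SimulationConfig(seed=1, depth=-5)
        with pytest.raises(ConfigError, match="genome_size"):
            generate_genes(SimulationConfig(seed=1, n_genes=100, genome_size=1e5))

    def test_config_hash_tracks_parameters(self):
        a = SimulationConfig(seed=1)
        b = SimulationConfig(seed=1, depth=300)
        assert a.config_hash() == SimulationConfig(seed=1).config_hash()
        assert a.config_hash() != b.config_hash()


class TestGenerateGenes:
    def test_same_seed_gives_byte_identical_bed(self, tmp_path):
        p1, p2 = tmp_path / "a.bed12", tmp_path / "b.bed12"
        write_bed12_genes(str(p1), generate_genes(SimulationConfig(seed=1, n_genes=10)).genes)
        write_bed12_genes(str(p2), generate_genes(SimulationConfig(seed=1, n_genes=10)).genes)
        assert p1.read_bytes() == p2.read_bytes()
        write_bed12_genes(str(p2), generate_genes(SimulationConfig(seed=2, n_genes=10)).genes)
        assert p1.read_bytes() != p2.read_bytes()

    def test_analysis_windows_pairwise_disjoint(self):
        sim = generate_genes(SimulationConfig(seed=3, n_genes=80))
        windows = []
        for g in sim.genes:
            windows.append(tssr_interval(g, sim.chrom_sizes))
            windows.append(body_interval(g, sim.chrom_sizes))
            windows.append(promoter_interval(g, chrom_sizes=sim.chrom_sizes))
        by_gene = [windows[i:i + 3] for i in range(0, len(windows), 3)]
        for i in range(len(by_gene)):
            for j in range(i + 1, len(by_gene)):
                for a in by_gene[i]:
                    for b in by_gene[j]:
                        assert a.overlap(b) == 0

    def test_both_strands_roughly_balanced(self):
        sim = generate_genes(SimulationConfig(seed=4, n_genes=1000))
        frac_plus = (sim.truth["strand"] == "+").mean()
        # binomial(1000, 0.5): +-4 sd band
        assert abs(frac_plus - 0.5) < 4 * 0.5 / np.sqrt(1000)


class TestRnapiiSimulation:
    @pytest.mark.parametrize("release,expected_pi", [(1.0, 1.0), (0.2, 5.0)])
    def test_median_pi_recovers_density_ratio(self, release, expected_pi):
        cfg = SimulationConfig(seed=11, n_genes=100, depth=500,
                               release_prob=release)
        sim = generate_genes(cfg)
        chip, inp = simulate_rnapii_experiment(sim, "control")
        records = pi_table(chip.to_track(sim.chrom_sizes),
                           inp.to_track(sim.chrom_sizes),
                           sim.genes, chrom_sizes=sim.chrom_sizes)
        med = np.median(defined_pi(records))
        assert abs(med - expected_pi) / expected_pi < 0.05

    def test_zero_background_gives_empty_input_and_all_defined(self):
        cfg = SimulationConfig(seed=12, n_genes=40, background_per_bp=0.0)
        sim = generate_genes(cfg)
        chip, inp = simulate_rnapii_experiment(sim, "control")
        assert len(inp.reads) == 0
        records = pi_table(chip.to_track(sim.chrom_sizes),
                           inp.to_track(sim.chrom_sizes),
                           sim.genes, chrom_sizes=sim.chrom_sizes)
        assert all(r.defined for r in records)

    def test_treatment_multiplier_lowers_pi_at_bound_genes(self):
        cfg = SimulationConfig(seed=13, n_genes=200, release_prob=0.25,
                               treatment_release_multiplier=2.0)
        sim = generate_genes(cfg)
        chip, inp = simulate_rnapii_experiment(sim, "treatment")
        records = pi_table(chip.to_track(sim.chrom_sizes),
                          inp.to_track(sim.chrom_sizes),
                          sim.genes, chrom_sizes=sim.chrom_sizes)
        pis = pd.Series({r.gene_id: r.pi for r in records if r.defined})
        bound = sim.truth.loc[pis.index, "bound"]
        assert np.median(pis[bound]) < np.median(pis[~bound]) * 0.75

    def test_reads_are_reproducible(self):
        cfg = SimulationConfig(seed=14, n_genes=20)
        a, _ = simulate_rnapii_experiment(generate_genes(cfg), "control")
        b, _ = simulate_rnapii_experiment(generate_genes(cfg), "control")
        pd.testing.assert_frame_equal(a.reads, b.reads)
        assert a.library_size == b.library_size


class TestPromoterChip:
    def test_noiseless_occupancy_tracks_expression(self):
        cfg = SimulationConfig(seed=21, n_genes=200, promoter_chip_noise_sd=0.0)
        sim = generate_genes(cfg)
        chip = simulate_promoter_chip(sim)
        track = chip.to_track(sim.chrom_sizes)
        from pausekit import SignalTrack
        empty = SignalTrack({c: np.zeros(s) for c, s in sim.chrom_sizes.items()},
                            library_size=1)
        table = promoter_signal_table(track, empty, sim.genes,
                                      chrom_sizes=sim.chrom_sizes)
        signal = np.array([r.signal for r in table])
        rho, _ = stats.spearmanr(signal, sim.truth["mu"].to_numpy())
        assert rho > 0.999  # exact up to integer count quantization

    def test_noisy_occupancy_weakens_correlation(self):
        cfg = SimulationConfig(seed=22, n_genes=500, promoter_chip_noise_sd=2.0)
        sim = generate_genes(cfg)
        chip = simulate_promoter_chip(sim)
        track = chip.to_track(sim.chrom_sizes)
        counts = np.array([track.count_reads(promoter_interval(g, chrom_sizes=sim.chrom_sizes))
                           for g in sim.genes])
        rho, _ = stats.spearmanr(counts, sim.truth["mu"].to_numpy())
        assert abs(rho) < 0.35  # near-independence limit


class TestSpikeinRnaseq:
    def test_depth_equalization_hides_amplification(self):
        sim = generate_genes(SimulationConfig(seed=31, n_genes=2000, amplification=1.3))
        table = simulate_spikein_rnaseq(sim)
        # sequenced fragment totals are exactly equalized ...
        counts = table.values.mul(table.lengths / 1e3, axis=0)
        totals = counts.sum()
        assert totals["treatment"] == pytest.approx(totals["control"], rel=1e-9)
        # ... so depth-normalized expression hides the global amplification
        from pausekit import median_log2_ratio
        assert abs(median_log2_ratio(table, "control", "treatment")) < 0.05

    def test_noiseless_doubling_recovered_exactly(self):
        from pausekit import loess_normalize_to_spikeins
        sim = generate_genes(SimulationConfig(seed=32, n_genes=500,
                                              amplification=2.0, dispersion=0.0))
        table = simulate_spikein_rnaseq(sim)
        norm = loess_normalize_to_spikeins(table, "control")
        genes = norm.genes()
        expressed = genes["control"] > 1.0
        ratio = np.log2(genes.loc[expressed, "treatment"]
                        / genes.loc[expressed, "control"])
        np.testing.assert_allclose(ratio, 1.0, atol=0.01)

    def test_spikein_rows_match_declared_pattern(self):
        sim = generate_genes(SimulationConfig(seed=33, n_genes=50))
        table = simulate_spikein_rnaseq(sim)
        assert table.is_spikein.sum() == 92
        assert all(i.startswith("ERCC-") for i in table.values.index[table.is_spikein])
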