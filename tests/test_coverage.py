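"""Coverage construction, density normalization, input subtraction, and
TSS-anchored signal matrices."""

import numpy as np
import pytest

from pausekit import (DataError, GenomicInterval, SignalTrack,
                      coverage_from_reads, net_density, region_density,
                      signal_matrix)

from conftest import make_gene, uniform_track


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestCoverageFromReads:
    def test_single_and_stacked_reads(self):
        track = coverage_from_reads([iv(100, 150)])
        assert track.coverage["chr1"][99] == 0
        assert (track.coverage["chr1"][100:150] == 1).all()
        track2 = coverage_from_reads([iv(100, 150), iv(100, 150)])
        assert (track2.coverage["chr1"][100:150] == 2).all()
        assert track2.library_size == 2

    def test_invalid_read_rejected(self):
        import pandas as pd
        reads = pd.DataFrame({"chrom": ["chr1"], "start": [150], "end": [100]})
        with pytest.raises(DataError, match="start >= end"):
            coverage_from_reads(reads)

    def test_matches_per_base_overlap_count(self, rng):
        """Per-base coverage equals a brute-force per-base overlap loop."""
        starts = rng.integers(0, 2000, 1000)
        lengths = rng.integers(1, 120, 1000)
        reads = [iv(int(s), int(s + l)) for s, l in zip(starts, lengths)]
        track = coverage_from_reads(reads)
        arr = track.coverage["chr1"]
        expected = np.array([
            sum(1 for r in reads if r.start <= b < r.end) for b in range(arr.size)])
        np.testing.assert_array_equal(arr, expected)

    def test_five_prime_mode_counts_read_starts(self):
        track = coverage_from_reads([iv(100, 150), iv(100, 180)],
                                    count_mode="five-prime")
        assert track.coverage["chr1"][100] == 2
        assert track.coverage["chr1"][101:180].sum() == 0


class TestRegionDensity:
    def test_uniform_coverage_unit_density(self):
        track = uniform_track(value=1, library_size=1_000_000)
        assert region_density(track, iv(100, 200)).density == pytest.approx(1.0)

    def test_empty_region_density_zero(self):
        track = coverage_from_reads([iv(100, 150)], library_size=10)
        assert region_density(track, iv(5000, 6000)).density == 0.0

    def test_partial_coverage_averages_over_length(self):
        cov = np.zeros(1000)
        cov[0:500] = 2
        track = SignalTrack({"chr1": cov}, library_size=2_000_000)
        assert region_density(track, iv(0, 1000)).density == pytest.approx(0.5)

    def test_unknown_chromosome_warns_and_returns_zero(self):
        track = uniform_track()
        with pytest.warns(UserWarning, match="not covered"):
            rd = region_density(track, iv(0, 100, chrom="chrUn"))
        assert rd.density == 0.0

    def test_normalization_invariance_under_depth_doubling(self, rng):
        reads = [iv(int(s), int(s) + 50) for s in rng.integers(0, 5000, 400)]
        t1 = coverage_from_reads(reads)
        t2 = coverage_from_reads(reads + reads)
        region = iv(1000, 2000)
        assert (region_density(t1, region).density
                == pytest.approx(region_density(t2, region).density))

    def test_split_region_length_weighted_average(self, rng):
        reads = [iv(int(s), int(s) + 50) for s in rng.integers(0, 5000, 400)]
        track = coverage_from_reads(reads)
        whole = region_density(track, iv(1000, 2000)).density
        left = region_density(track, iv(1000, 1300)).density
        right = region_density(track, iv(1300, 2000)).density
        assert whole == pytest.approx((300 * left + 700 * right) / 1000)

    def test_raw_read_count_recovered(self):
        track = coverage_from_reads([iv(100, 150), iv(140, 190), iv(500, 550)])
        assert region_density(track, iv(120, 160)).raw_reads == 2


class TestNetDensity:
    def test_examples(self):
        region = iv(0, 100)
        mk = lambda d: region_density(
            SignalTrack({"chr1": np.full(100, d, dtype=float)}, 1_000_000), region)
        assert net_density(mk(5.0), mk(1.0)).net == pytest.approx(4.0)
        assert net_density(mk(5.0), mk(1.0)).valid
        # signal equal to input: net 0 is invalid (PI undefined downstream)
        assert not net_density(mk(1.0), mk(1.0)).valid
        assert not net_density(mk(0.5), mk(1.0)).valid

    def test_mismatched_regions_rejected(self):
        track = uniform_track()
        with pytest.raises(DataError, match="identical regions"):
            net_density(region_density(track, iv(0, 100)),
                        region_density(track, iv(0, 200)))


class TestSignalMatrix:
    def test_delta_at_anchor_hits_center(self):
        cov = np.zeros(10_000)
        cov[5000:5010] = 100.0
        track = SignalTrack({"chr1": cov}, library_size=1_000_000)
        gene = make_gene(start=5000, end=8000, strand="+")
        res = signal_matrix(track, [gene], window=2000, bin_size=25)
        hot = np.flatnonzero(res.matrix[0])
        assert set(hot) == {80}  # first bin right of the anchor

    def test_minus_strand_orients_downstream_rightward(self):
        cov = np.zeros(10_000)
        cov[4900:4950] = 10.0  # downstream of a minus-strand TSS at 5000
        track = SignalTrack({"chr1": cov}, library_size=1_000_000)
        gene = make_gene(start=2000, end=5000, strand="-")
        res = signal_matrix(track, [gene], window=2000, bin_size=25)
        center = res.matrix.shape[1] // 2
        assert res.matrix[0, :center].sum() == 0
        assert res.matrix[0, center:].sum() > 0

    def test_profile_matches_naive_binning(self, rng):
        reads = [iv(int(s), int(s) + 50) for s in rng.integers(0, 100_000, 5000)]
        track = coverage_from_reads(reads)
        genes = [make_gene(f"g{i}", "chr1", int(s), int(s) + 3000,
                           "+" if i % 2 else "-")
                 for i, s in enumerate(rng.integers(3000, 90_000, 100))]
        res = signal_matrix(track, genes, window=2000, bin_size=25)
        arr = track.coverage["chr1"]
        naive = []
        for g in genes:
            lo, hi = g.tss - 2000, g.tss + 2000
            win = np.zeros(4000)
            s, e = max(lo, 0), min(hi, arr.size)
            win[s - lo:e - lo] = arr[s:e]
            if g.strand == "-":
                win = win[::-1]
            naive.append(win.reshape(-1, 25).mean(axis=1) * 1e6 / track.library_size)
        np.testing.assert_allclose(res.profile, np.mean(naive, axis=0), rtol=1e-12)

    def test_ordering_permutes_rows_without_changing_content(self, rng):
        reads = [iv(int(s), int(s) + 50) for s in rng.integers(0, 50_000, 2000)]
        track = coverage_from_reads(reads)
        genes = [make_gene(f"g{i}", "chr1", int(s), int(s) + 2500)
                 for i, s in enumerate(rng.integers(3000, 40_000, 30))]
        base = signal_matrix(track, genes, window=1000, bin_size=25)
        ranked = signal_matrix(track, genes, window=1000, bin_size=25,
                               order_by=rng.random(30))
        assert sorted(base.row_ids) == sorted(ranked.row_ids)
        # row multiset identical: sum over rows invariant to ordering
        np.testing.assert_allclose(base.matrix.sum(axis=0),
                                   ranked.matrix.sum(axis=0), rtol=1e-12)
        lookup = {rid: row for rid, row in zip(base.row_ids, base.matrix)}
        for rid, row in zip(ranked.row_ids, ranked.matrix):
            np.testing.assert_array_equal(row, lookup[rid])

    def test_empty_references_rejected(self):
        with pytest.raises(DataError):
            signal_matrix(uniform_track(), [], window=1000, bin_size=25)

    def test_window_bin_divisibility_enforced(self):
        with pytest.raises(DataError, match="divisible"):
            signal_matrix(uniform_track(), [make_gene()], window=1000, bin_size=33)
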