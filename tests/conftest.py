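import numpy as np
import pytest

from pausekit import GeneModel, GenomicInterval, SignalTrack


def make_gene(gene_id="geneA", chrom="chr1", start=1000, end=5000, strand="+"):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand))


def uniform_track(chrom="chr1", size=10_000, value=1, library_size=1_000_000,
                  label="uniform"):
    """A track with constant per-base coverage, for closed-form density checks."""
    return SignalTrack({chrom: np.full(size, value, dtype=float)},
                       library_size=library_size, label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def gene_plus():
    return make_gene("geneP", "chr1", 1000, 5000, "+")


@pytest.fixture
def gene_minus():
    return make_gene("geneM", "chr1", 1000, 5000, "-")
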