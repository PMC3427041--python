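import numpy as np
import pytest

from homeopipe import simgen
from homeopipe.contigspace import AlignedRead, ContigAlignment


@pytest.fixture(scope="session")
def clean_dataset():
    """Small error-free dataset with default branch evolution, no NRHR."""
    cfg = simgen.SimConfig(
        n_contigs=8,
        seed=42,
        long_err=0.0,
        short_err=0.0,
        nrhr_contig_frac=0.0,
        long_cov=12,
        short_cov=20,
    )
    return simgen.simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_read(read_id, species, start, bases, platform="long", quals=None):
    q = None if quals is None else np.asarray(quals, dtype=np.int16)
    return AlignedRead(read_id, species, platform, start, bases, q)


@pytest.fixture()
def tiny_alignment():
    """Hand-built 10-bp contig with a known pileup."""
    aln = ContigAlignment("c1", 10)
    aln.add_read(make_read("A2|r1", "A2", 0, "ACGTACGTAC"))
    aln.add_read(make_read("A2|r2", "A2", 2, "GTACGT"))
    aln.add_read(make_read("D5|r1", "D5", 0, "ACGTTCGTAC"))
    return aln
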