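import numpy as np
import pytest

from cibmut.genomic_io import Genome, GenomeSequence
from cibmut.synthetic_data import generate_genome, generate_mutations, packaged_profiles


def make_genome(sequence: str, name: str = "chr1") -> Genome:
    return Genome([GenomeSequence(name, sequence)])


@pytest.fixture(scope="session")
def synthetic_genome():
    """Deterministic 100 kb genome with seeded repeat context and 20 genes."""
    return generate_genome(length=100_000, n_genes=20, seed=11)


@pytest.fixture(scope="session")
def lig4_bundle(synthetic_genome):
    """Calls + truth for the lig4-4-like profile on the shared genome."""
    genome, models = synthetic_genome
    profile = packaged_profiles()["lig4-4-100Gy"]
    calls, truths = generate_mutations(genome, models, profile, seed=11)
    return genome, models, profile, calls, truths


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
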