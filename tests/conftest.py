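"""Shared fixtures: small synthetic genomes and gene models built at test time."""

import numpy as np
import pytest

from retromap.genome_annotation import GeneIndex, GeneModel
from retromap.random_controls import build_restriction_map
from retromap.synthetic_data import SyntheticConfig, simulate_genes, simulate_genome


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        seed=7,
        genome_length=200_000,
        n_chromosomes=2,
        n_genes=20,
        n_sites=200,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    genome, rmap = simulate_genome(small_config)
    return genome, rmap


@pytest.fixture(scope="session")
def small_genes(small_genome, small_config):
    genome, _ = small_genome
    genes, expression = simulate_genes(genome, small_config)
    return genes, expression


@pytest.fixture()
def toy_genes():
    """Hand-built gene models on one chromosome for exact annotation checks."""
    return [
        GeneModel("tA.1", "gA", "gA", "chr1", "+", 10_000, 30_000),
        GeneModel("tB.1", "gB", "gB", "chr1", "-", 60_000, 80_000),
        GeneModel("tC.1", "gC", "gC", "chr1", "+", 1_000, 9_500),
        GeneModel("tC.2", "gC", "gC", "chr1", "+", 9_000, 9_500),
    ]


@pytest.fixture()
def toy_index(toy_genes):
    return GeneIndex(toy_genes)


@pytest.fixture()
def uniform_genome():
    """A 100 kb single-chromosome genome with a fixed seed."""
    rng = np.random.default_rng(11)
    seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=100_000))
    genome = {"chr1": seq}
    return genome, build_restriction_map(genome)
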