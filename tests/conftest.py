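"""Shared fixtures: a small seeded genome, error-bearing scaffolds, alignments.

Session-scoped so the synthetic world is built once; individual tests that
need different parameters build their own.
"""

import pytest

from asmrecon.fragment_align import align_scaffolds
from asmrecon.synthetic_data import (
    ClusterSpec,
    GenomeConfig,
    ScaffoldErrorConfig,
    simulate_genome,
    simulate_scaffolds,
)

GENOME_CONFIG = GenomeConfig(
    n_chromosomes=3,
    chrom_length=200_000,
    n_genes=90,
    cluster_specs=(ClusterSpec(29, 73_000), ClusterSpec(38, 75_000), ClusterSpec(3, 6_000)),
    seed=11,
)

ERROR_CONFIG = ScaffoldErrorConfig(
    n_misjoin=3,
    n_inversion=2,
    n_deletion=3,
    n_insertion=2,
    n_small_deletion=1,
    n_small_insertion=1,
    n_small_inversion=1,
    small_indel_rate=1e-4,
    seed=13,
)


@pytest.fixture(scope="session")
def genome():
    return simulate_genome(GENOME_CONFIG)


@pytest.fixture(scope="session")
def errored(genome):
    """Scaffolds with a known planted-event roster plus its truth table."""
    return simulate_scaffolds(genome, ERROR_CONFIG)


@pytest.fixture(scope="session")
def errored_fragments(genome, errored):
    return align_scaffolds(errored.scaffolds, genome.chromosomes)


@pytest.fixture(scope="session")
def perfect_fragments(genome):
    """Fragments of the error-free scaffolds (the chromosomes themselves)."""
    scaffolds = {f"s{i}": seq for i, seq in enumerate(genome.chromosomes.values(), 1)}
    return align_scaffolds(scaffolds, genome.chromosomes)
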