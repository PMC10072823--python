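import numpy as np
import pytest

from mitoevo.model import default_genome
from mitoevo.simulate import CohortConfig, LocusSpec, generate_cohort


@pytest.fixture(scope="session")
def genome():
    return default_genome()


@pytest.fixture(scope="session")
def small_catalog(genome):
    """Six loci on distinct chromosomes; snv-only mix keeps annotations clean."""
    chroms = genome.nuclear_chroms
    return [
        LocusSpec(f"g{i+1}", chroms[i % len(chroms)], 1 + 1000 * i, 1000 + 1000 * i,
                  base_rate=0.2)
        for i in range(6)
    ]


@pytest.fixture(scope="session")
def small_cohort(genome, small_catalog):
    cfg = CohortConfig(
        genotypes=("NN", "ND", "DN", "DD"),
        media=("FF", "NF"),
        replicates_per_circumstance=12,
        locus_catalog=small_catalog,
        mutation_type_mix={"SNV": 1.0},
        extinction_probability=0.0,
        seed=11,
        genome=genome,
    )
    meta, calls, truth = generate_cohort(cfg)
    return meta, calls, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
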