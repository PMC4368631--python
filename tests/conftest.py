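import numpy as np
import pandas as pd
import pytest

from promdiff.promoters import PromoterCountMatrix
from promdiff.simulate import SimulationConfig, assign_archetypes, simulate_genome


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale study: 200 genes, 2 chromosomes, shallow libraries."""
    return SimulationConfig(
        n_genes=200,
        n_chroms=2,
        chrom_length=300_000,
        library_size=20_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_genome):
    _sizes, genes = small_genome
    return assign_archetypes(genes, small_config)


def make_count_matrix(counts, groups=("patient", "patient", "control", "control"), mark="H3K4me3"):
    counts = np.asarray(counts)
    sample_ids = [f"S{i}" for i in range(counts.shape[1])]
    return PromoterCountMatrix(
        mark=mark,
        gene_ids=[f"g{i}" for i in range(counts.shape[0])],
        sample_ids=sample_ids,
        groups=dict(zip(sample_ids, groups)),
        counts=counts,
    )
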