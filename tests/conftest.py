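import numpy as np
import pandas as pd
import pytest

from somre.calling import GenomeIndex
from somre.simulate import (
    SimulationConfig,
    build_genome,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact five-tissue, L1-only configuration for fast unit tests."""
    return SimulationConfig(
        families=("L1Hs",),
        chrom_lengths={"chr1": 100_000, "chr2": 100_000, "chr3": 100_000},
        ref_re_count=8,
        germline_count=8,
        somatic_rate_per_mb=60.0,
        read_depth=10.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_run(small_config):
    """One deterministic simulated experiment shared across tests."""
    return simulate_experiment(small_config, seed=5)


@pytest.fixture(scope="session")
def small_genome(small_run):
    return small_run[0]


@pytest.fixture(scope="session")
def small_index(small_genome) -> GenomeIndex:
    return GenomeIndex(small_genome)


@pytest.fixture(scope="session")
def medium_genome():
    """A 3 x 1 Mb genome with default annotation density."""
    return build_genome(SimulationConfig(), seed=1)


def make_genes(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
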