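import numpy as np
import pytest

import migradiv as mg


@pytest.fixture(scope="session")
def blackcap():
    """Published survey tables: (metadata list, dest matrix, distance matrix)."""
    dest, dist = mg.blackcap_differentiation()
    return mg.blackcap_metadata(), dest, dist


@pytest.fixture(scope="session")
def small_pair_table():
    """Two moderately diverged populations of 30, 14 loci."""
    cfg = mg.SimulationConfig(seed=421, sizes=(30, 30), divergence=0.1)
    table, freqs = mg.sim_genotypes(cfg)
    return table, freqs


def make_table(records, loci=None):
    """Tiny GenotypeTable from nested python lists."""
    loci = loci or [f"L{i+1}" for i in range(len(next(iter(records.values()))[0]))]
    return mg.GenotypeTable.from_records(records, loci)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
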