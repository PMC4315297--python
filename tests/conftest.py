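"""Session-scoped synthetic datasets shared across the suite."""

import numpy as np
import pytest

from p4rna.pipeline import run_pipeline
from p4rna.simulate import SimulationConfig, simulate

#: one simulation at the default study conditions drives most checks
SIM_SEED = 1


@pytest.fixture(scope="session")
def sim():
    return simulate(SimulationConfig(seed=SIM_SEED))


@pytest.fixture(scope="session")
def pipeline(sim):
    return run_pipeline(sim=sim)


@pytest.fixture(scope="session")
def fold4_sim():
    """A dataset with an exactly fourfold planted Pol IV depletion."""
    return simulate(SimulationConfig(seed=2, p4_fold_change=4.0))


@pytest.fixture(scope="session")
def small_config():
    """A miniature configuration for end-to-end determinism runs."""
    return SimulationConfig(
        seed=11,
        genome_size=60_000,
        n_p4_loci=24,
        n_pol2_loci=6,
        n_genes=10,
        default_depth=20_000,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20259)
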