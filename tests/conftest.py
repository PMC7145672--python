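import numpy as np
import pytest

from retroscape.pipeline import PipelineConfig, run_full
from retroscape.simgenome import SimulationConfig, simulate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=7,
        scaffold_lengths=(400_000, 300_000),
        n_genes=60,
        n_elements=40,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_pipeline(small_config):
    """One small end-to-end run shared by the integration tests."""
    return run_full(PipelineConfig(sim=small_config))
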