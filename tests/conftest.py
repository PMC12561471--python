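import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from splicescan.synthetic_data import SimulationConfig, make_genome, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """A modest synthetic dataset shared across tests (read-only)."""
    config = SimulationConfig(seed=11, n_genes=100, n_events_up=10, n_events_down=5)
    genome, genes, truth = make_genome(config)
    return config, genome, genes, truth


@pytest.fixture(scope="session")
def small_counts(small_sim):
    config, _, _, truth = small_sim
    return simulate_counts(truth, config)
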