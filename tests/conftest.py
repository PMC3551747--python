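import pytest

from osedax16s.datasets import (
    load_contingency_tables,
    load_dilution_calls,
    load_worm_dissections,
)
from osedax16s.synthetic_data import SimulationConfig, generate_ribospecies_pool


@pytest.fixture(scope="session")
def contingency_tables():
    return load_contingency_tables()


@pytest.fixture(scope="session")
def dissected_worms():
    return load_worm_dissections()


@pytest.fixture(scope="session")
def dilution_calls():
    return load_dilution_calls()


@pytest.fixture(scope="session")
def small_pool():
    """Two ribospecies of five ribotypes each, default divergence regime."""
    config = SimulationConfig(seed=1, n_ribospecies=2, ribotypes_per_species=5)
    return generate_ribospecies_pool(config)
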