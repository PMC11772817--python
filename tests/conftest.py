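import pytest

from secsig import (
    SimulationConfig,
    simulate_annotation,
    simulate_array,
    simulate_counts,
    simulate_qpcr,
    upper_quartile_normalize,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Small but structurally complete synthetic study."""
    return SimulationConfig.default(
        n_planted=10, n_genes=300, n_per_group=3, n_array_targets=30, seed=7
    )


@pytest.fixture(scope="session")
def counts(small_config):
    return simulate_counts(small_config)


@pytest.fixture(scope="session")
def normalized(counts):
    return upper_quartile_normalize(counts)


@pytest.fixture(scope="session")
def annotation_db(small_config):
    return simulate_annotation(small_config)


@pytest.fixture(scope="session")
def array_experiment(small_config):
    return simulate_array(small_config)


@pytest.fixture(scope="session")
def ct_table(small_config):
    return simulate_qpcr(small_config)
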