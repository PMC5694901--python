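"""Shared fixtures: a small simulated study reused across test modules."""
import numpy as np
import pytest

from starrkit.simulate import (
    SimulationConfig,
    simulate_expression_and_tsa,
    simulate_fragment_libraries,
    simulate_genome,
)


@pytest.fixture(scope="session")
def small_config():
    # modest depth, fixed activity: fast but deep enough for recovery checks
    return SimulationConfig(
        seed=11,
        n_enhancers=60,
        activity_fixed=4.0,
        n_input_fragments=120_000,
        n_output_fragments=120_000,
        n_genes=120,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_libraries(small_config, small_truth):
    input_set, output_set = simulate_fragment_libraries(small_config, small_truth)
    return (
        input_set,
        output_set,
        input_set.dedup_pool("input"),
        output_set.dedup_pool("output"),
    )


@pytest.fixture(scope="session")
def small_expression(small_config, small_truth):
    return simulate_expression_and_tsa(small_config, small_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
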