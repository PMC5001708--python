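import numpy as np
import pytest
from hypothesis import settings

from rewardglm import GlmConfig, build_design_matrix
from rewardglm.simulate import (SimulationConfig, default_neuron_specs,
                                simulate_session)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_session():
    """60-trial, 3-neuron benchmark session shared across read-only tests."""
    cfg = SimulationConfig(n_trials=60, neuron_specs=default_neuron_specs(3),
                           seed=11)
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def small_design(small_session):
    return build_design_matrix(small_session)


@pytest.fixture(scope="session")
def bench_session():
    """Mid-size benchmark session for GLM/battery tests (200 trials, 4 neurons)."""
    cfg = SimulationConfig(n_trials=200, neuron_specs=default_neuron_specs(4),
                           seed=21)
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def bench_design(bench_session):
    return build_design_matrix(bench_session)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def fast_glm_cfg():
    return GlmConfig()
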