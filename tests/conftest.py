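import numpy as np
import pytest

from loopdep import (
    DesignConfig,
    GenerativeConfig,
    build_encoding_schedule,
    build_event_set,
    build_retrieval_schedule,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def design_config():
    return DesignConfig()


@pytest.fixture(scope="session")
def event_set(design_config):
    return build_event_set(design_config, np.random.default_rng(42))


@pytest.fixture(scope="session")
def encoding_schedule(event_set, design_config):
    return build_encoding_schedule(event_set, design_config, np.random.default_rng(7))


@pytest.fixture(scope="session")
def retrieval_schedule(event_set, design_config):
    return build_retrieval_schedule(event_set, design_config, np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_cohort():
    """Six simulated participants sharing one event set (fast fixture)."""
    design = DesignConfig(shared_event_set=True)
    gen = GenerativeConfig(n_participants=6)
    return simulate_cohort(design, gen, seed=123)
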