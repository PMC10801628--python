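import pytest

from srnacore.simulate import (
    SimulationConfig,
    make_toy_references,
    simulate_environment_sample,
    simulate_reads,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=7, reads_per_sample=600, n_test=2, n_control=2)


@pytest.fixture(scope="session")
def refs(sim_config):
    return make_toy_references(sim_config)


@pytest.fixture(scope="session")
def samples(refs, sim_config):
    return simulate_reads(refs, sim_config)


@pytest.fixture(scope="session")
def environment(refs, sim_config, samples):
    env_reads, planted = simulate_environment_sample(refs, sim_config, samples)
    return env_reads, planted


@pytest.fixture(scope="session")
def taxonomy(refs):
    return refs.taxonomy
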