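import pytest

from primesplit.chemistry import load_chemistry_table
from primesplit.simulate import SimulationConfig, generate_experiment


@pytest.fixture(scope="session")
def chemistry():
    """The packaged measured litter chemistry (3 species + 4 mixtures)."""
    return load_chemistry_table()


@pytest.fixture(scope="session")
def noiseless_config():
    return SimulationConfig(
        seed=123,
        priming_jar_sd=0.0,
        base_jar_sd=0.0,
        decay_jar_sd=0.0,
        toc_meas_sd=0.0,
        d13c_meas_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_experiment(noiseless_config):
    return generate_experiment(noiseless_config)


@pytest.fixture(scope="session")
def default_experiment():
    return generate_experiment(SimulationConfig(seed=123))
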