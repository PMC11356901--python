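import pytest

from msescreen.io import load_fixture
from msescreen.simulate import SimConfig, generate_library, simulate_runs


@pytest.fixture(scope="session")
def fixture_table():
    return load_fixture()


@pytest.fixture(scope="session")
def sim():
    """A seeded synthetic experiment: (config, library, truth, runs)."""
    config = SimConfig(seed=11, n_decoys=10)
    library, truth = generate_library(config)
    runs = simulate_runs(library, truth, config)
    return config, library, truth, runs
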