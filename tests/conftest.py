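import pytest

from fermgenomics.study_model import load_table1
from fermgenomics.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated study (3099 genes, 29 profiled
    fermentors, all planted structures), shared across tests."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    """A cheaper 600-gene study for tests that only need the shapes."""
    return simulate_study(SimulationConfig(n_genes=600, seed=7))
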