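import pytest
from hypothesis import settings

from ire_screen.synthetic_data import SimulationConfig, simulate_all

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """One full synthetic dataset at the default study conditions."""
    return simulate_all(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down configuration for file-level tests."""
    return SimulationConfig(
        seed=7, n_genes=20, n_intronic_peaks=20, n_promoter_peaks=20,
        n_intergenic_peaks=19, deg_counts=(4, 2), n_patients=30,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_all(small_config)
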