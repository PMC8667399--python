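import pytest

from loyprs.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down cohort that keeps every downstream stage estimable."""
    return SimulationConfig(n_samples=400, n_wgs_samples=120, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)
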