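import pytest

from synotrial import SimulationConfig, simulate_trial


@pytest.fixture(scope="session")
def default_trial():
    """One default-size synthetic trial shared across read-only tests."""
    return simulate_trial(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_trial():
    """A small expression-free trial for cheap structural tests."""
    return simulate_trial(
        SimulationConfig(n_patients=60, with_expression=False, seed=7)
    )
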