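import numpy as np
import pytest

from sleepreg.simulate import SimulationSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    """A reduced cohort with noise-free diaries, shared across tests."""
    return SimulationSpec(n_stroke=12, n_control=8, seed=42, diary_noise_sd=0.0)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return simulate_cohort(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
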