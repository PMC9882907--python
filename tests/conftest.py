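import numpy as np
import pytest
from hypothesis import settings

import mndpath as m

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return m.generate_baseline_config("default-calibrated")


@pytest.fixture(scope="session")
def fast_config():
    return m.generate_baseline_config("fast-test")


@pytest.fixture(scope="session")
def default_cohort(default_config):
    """One shared 100k-patient baseline cohort (expensive; session scope)."""
    return m.simulate_cohort(default_config, 100_000, seed=2024)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
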