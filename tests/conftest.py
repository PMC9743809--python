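import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def small_session():
    """One synthetic session shared by read-only tests."""
    from cogload.simulate import simulate_session

    return simulate_session(101, seed=5)


@pytest.fixture(scope="session")
def small_cohort():
    """A four-person cohort without device dropouts."""
    from cogload.simulate import simulate_cohort

    return simulate_cohort(4, seed=5)
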