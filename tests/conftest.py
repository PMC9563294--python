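import numpy as np
import pytest

from tplnz import AdamConfig, TplnzParams, tplnz_rng, wind_speed


@pytest.fixture(scope="session")
def wind():
    return wind_speed()


@pytest.fixture(scope="session")
def profile_cfg():
    """Adam settings ascending the canonical profile log-likelihood."""
    return AdamConfig(objective="profile")


@pytest.fixture(scope="session")
def interior_sample():
    """Large synthetic sample with an interior threshold mode (gamma = 3)."""
    return tplnz_rng(TplnzParams(gamma=3.0, mu=1.0, sigma2=1.25, rho=0.9),
                     n=5600, seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
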