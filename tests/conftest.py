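import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def brazil_bundle():
    from smokesim import make_brazil_like_fixture
    return make_brazil_like_fixture(seed=7)


@pytest.fixture(scope="session")
def brazil_model(brazil_bundle):
    from smokesim import TobaccoPolicyModel
    return TobaccoPolicyModel.from_bundle(brazil_bundle)


@pytest.fixture(scope="session")
def fitted(brazil_model):
    """Standard scenario set on the Brazil-like bundle (shared: runs once)."""
    return brazil_model.fit()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
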