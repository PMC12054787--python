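import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_encoding_params():
    """Small (5-voxel) generative model used across encoding tests."""
    from contextfi.synthetic import random_encoding_params

    return random_encoding_params(5, seed=11, channel_sd=0.2, rho=0.1)


@pytest.fixture(scope="session")
def cardinal_fi():
    """Cardinal-peaked FI profile at default study conditions."""
    from contextfi.synthetic import gen_prior

    return gen_prior("cardinal_peaked").to_fi_profile(50.0)
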