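import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dentaltopo import synthetic


@pytest.fixture(scope="session")
def icosphere3():
    return synthetic.make_icosphere(3)


@pytest.fixture(scope="session")
def hemisphere3():
    return synthetic.make_hemisphere(3)


@pytest.fixture(scope="session")
def flat_plane():
    return synthetic.make_plane(11, 11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160203)
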