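import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import conespect as cs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol():
    return cs.default_protocol()


@pytest.fixture(scope="session")
def wt_larva():
    return cs.preset("wt_larva")


@pytest.fixture(scope="session")
def het_larva():
    return cs.preset("het_6bp1_larva")


@pytest.fixture(scope="session")
def mut_larva():
    return cs.preset("mut_6bp1_larva")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
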