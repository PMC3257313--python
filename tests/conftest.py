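import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from cbckit import find_steady_state
from cbckit.fixtures import toy_cycle_fixture
from cbckit.model_library import build_model


@pytest.fixture(scope="session")
def cyano_c2():
    return build_model("cyano_C2")


@pytest.fixture(scope="session")
def cyano_c2_steady(cyano_c2):
    return find_steady_state(cyano_c2)


@pytest.fixture(scope="session")
def toy_cycle():
    return toy_cycle_fixture()


@pytest.fixture(scope="session")
def toy_cycle_steady(toy_cycle):
    return find_steady_state(toy_cycle)
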