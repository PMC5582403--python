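import numpy as np
import pytest

from burstfit import ParameterSet, StateSpace, build_two_state_model, truth_presets


@pytest.fixture(scope="session")
def two_state():
    return build_two_state_model(2)


@pytest.fixture(scope="session")
def theta_basic():
    return {"k1": 0.01, "k0": 0.1, "mu0": 0.01, "mu1": 2.0, "delta": 0.05}


@pytest.fixture(scope="session")
def k1_preset() -> ParameterSet:
    return truth_presets()["k1_stim"]


@pytest.fixture(scope="session")
def small_space(two_state) -> StateSpace:
    return StateSpace(M=100, p=two_state.p)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
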