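import numpy as np
import pytest

from circabeam.light import build_regime


@pytest.fixture(scope="session")
def dd_regime():
    return build_regime("DD")


@pytest.fixture(scope="session")
def spp_regime():
    return build_regime("SPP", {"intensity": 450, "units": "lux"})


@pytest.fixture(scope="session")
def ramp_regime():
    return build_regime("RAMP", {"i_min": 10, "i_max": 45})


@pytest.fixture()
def rng():
    return np.random.default_rng(20230913)
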