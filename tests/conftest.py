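import numpy as np
import pytest

from sonosim import GeneratorConfig, WATER, get_preset


@pytest.fixture(scope="session")
def water():
    return WATER


@pytest.fixture(scope="session")
def preset_05():
    return get_preset("0.5MHz")


@pytest.fixture(scope="session")
def preset_225():
    return get_preset("2.25MHz")


@pytest.fixture(scope="session")
def preset_15():
    return get_preset("15MHz")


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig(seed=12345)


@pytest.fixture()
def rng():
    return np.random.default_rng(987)
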