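import numpy as np
import pytest

from meshffd.synthetic import make_texture


@pytest.fixture(scope="session")
def texture64():
    return make_texture(6, 64, 64)


@pytest.fixture(scope="session")
def texture64b():
    return make_texture(7, 64, 64)


@pytest.fixture(scope="session")
def texture128():
    return make_texture(11, 128, 128)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
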