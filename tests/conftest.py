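import numpy as np
import pytest

from fundusgan.phantom import PhantomParams, generate_sample


@pytest.fixture(scope="session")
def params64():
    return PhantomParams(image_size=64, seed=0)


@pytest.fixture(scope="session")
def sample64(params64):
    return generate_sample(params64)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
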