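import numpy as np
import pytest

import ewistars as ew


@pytest.fixture(scope="session")
def phantom64():
    return ew.make_phantom(ew.PhantomSpec(size=(64, 64), seed=0))


@pytest.fixture(scope="session")
def phantom128():
    return ew.make_phantom(ew.PhantomSpec(size=(128, 128), seed=0))


@pytest.fixture(scope="session")
def mask64():
    return ew.make_mask((64, 64), 5.0, seed=3)


@pytest.fixture(scope="session")
def kspace64(phantom64, mask64):
    return ew.forward_model(phantom64, mask64, 0.01, seed=4)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
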