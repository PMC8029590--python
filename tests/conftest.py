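import numpy as np
import pytest

from mvfcm.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Clean 128x128 four-class phantom with its label map."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def small_phantom():
    """64x64 phantom for fast pipeline tests."""
    return generate_phantom(PhantomSpec(size=(64, 64)))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
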