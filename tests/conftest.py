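import numpy as np
import pytest

from mmalign import make_base_image


@pytest.fixture(scope="session")
def base_image():
    """A 256x256 vessel-like scene shared by the heavier tests."""
    return make_base_image(256, 12, seed=0)


@pytest.fixture(scope="session")
def small_scene():
    """A smaller scene for quick detector/matcher tests."""
    return make_base_image(160, 8, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
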