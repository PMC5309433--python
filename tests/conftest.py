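import numpy as np
import pytest

from hlacir import CENTER_NO_REPEAT, FULL_GRAYSCALE, enumerate_masks


@pytest.fixture(scope="session")
def maskset25():
    return enumerate_masks(2, CENTER_NO_REPEAT)


@pytest.fixture(scope="session")
def maskset35():
    return enumerate_masks(2, FULL_GRAYSCALE)


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture()
def random_gray(rng):
    """A seeded 20x20 uint8 gray image."""
    return rng.integers(0, 256, (20, 20), dtype=np.uint8)
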