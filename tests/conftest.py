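import numpy as np
import pytest
from hypothesis import settings

from iqrank import GrayImage, make_base_image

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_image(rng):
    return GrayImage(rng.uniform(0, 255, (64, 64)))


@pytest.fixture
def beads_image():
    return make_base_image("beads", (128, 128), seed=1)


@pytest.fixture
def filaments_image():
    return make_base_image("filaments", (128, 128), seed=2)
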