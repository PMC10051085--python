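import numpy as np
import pytest

import lesionseg as ls


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_sample(rng):
    """A 32x32 sample with a centered square lesion."""
    image = rng.random((32, 32, 3)).astype(np.float32)
    mask = np.zeros((32, 32), dtype=np.uint8)
    mask[10:22, 8:20] = 1
    return ls.ImageSample(image=image, mask=mask, identifier="square")


@pytest.fixture(scope="session")
def tiny_config():
    return ls.ModelConfig(architecture="attresunet", input_size=(32, 32), depth=2, base_filters=4)


def random_binary_mask(rng, shape=(16, 16), p=0.5):
    return (rng.random(shape) < p).astype(np.uint8)
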