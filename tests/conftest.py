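import numpy as np
import pytest

from skinspace import RgbImage, SceneConfig, SkinMask, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    return RgbImage(rng.random((8, 11, 3)))


@pytest.fixture
def random_pixels(rng):
    return rng.random((1000, 3))


@pytest.fixture
def scene_pair():
    return generate_scene(SceneConfig(seed=7))


@pytest.fixture
def checker_masks():
    truth = SkinMask((np.indices((6, 6)).sum(axis=0) % 2).astype(np.uint8))
    pred = SkinMask(np.roll(truth.labels, 1, axis=1))
    return pred, truth
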