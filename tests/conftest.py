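import numpy as np
import pytest

from mipanomaly.detector import BackboneConfig, TrainConfig, train
from mipanomaly.phantom import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_config() -> PhantomConfig:
    """Small, fast cohort: 32x32 phantoms, ~100 breasts."""
    return PhantomConfig(image_height=32, image_width=32, n_patients=30, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    manifest, images = generate_cohort(tiny_config)
    return manifest, images


@pytest.fixture(scope="session")
def tiny_arrays(tiny_cohort):
    manifest, images = tiny_cohort
    data = {img.image_id: img for img in images}
    ids = [img.image_id for img in images]
    x = np.stack([data[i].canonical_pixels() for i in ids])
    y = np.array([data[i].label for i in ids], dtype=float)
    return ids, x, y, data


@pytest.fixture(scope="session")
def small_backbone() -> BackboneConfig:
    return BackboneConfig(channels=(4, 8, 8), strides=(1, 2, 2), seed=5)


@pytest.fixture(scope="session")
def trained_small_fcdd(tiny_arrays, small_backbone):
    _, x, y, _ = tiny_arrays
    return train("fcdd", x, y, small_backbone, TrainConfig(epochs=4, seed=2))
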