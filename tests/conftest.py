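import numpy as np
import pytest

from colposeg import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def synth_default():
    """Ten default-condition synthetic images with ground-truth masks."""
    pairs = generate_dataset(SyntheticSpec(), 10)
    images = np.stack([p[0] for p in pairs])
    masks = [p[1] for p in pairs]
    return images, masks


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def random_response(rng, h, w, k):
    z = rng.random((h, w, k)) + 1e-3
    return z / z.sum(axis=-1, keepdims=True)


@pytest.fixture()
def make_response():
    return random_response
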