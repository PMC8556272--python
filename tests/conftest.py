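"""Shared fixtures: random images and small phantoms built at test time."""

import numpy as np
import pytest

from nsmuscle.ns_core import MultiChannelImage, normalize_channels

RGB_ROLES = {"red": 0, "green": 1, "blue": 2}


def make_rgb(pixels, normalized=False, **kw) -> MultiChannelImage:
    img = MultiChannelImage(np.asarray(pixels, float), dict(RGB_ROLES), **kw)
    img.normalized = normalized
    return img


def random_rgb(rng, h=16, w=16) -> MultiChannelImage:
    """Random image whose channels each span [0, 1] exactly."""
    px = rng.random((h, w, 3))
    return normalize_channels(MultiChannelImage(px, dict(RGB_ROLES)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_polygonal():
    """25-fiber noiseless polygonal phantom shared across tests."""
    from nsmuscle.phantom import PhantomSpec, generate
    spec = PhantomSpec(image_size=(512, 512), n_fibers=25, seed=42)
    img, gt = generate(spec)
    return spec, img, gt
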