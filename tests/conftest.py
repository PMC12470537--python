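import numpy as np
import pytest

from ctiq.io_formats import ImageGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def structured_pixels(rng, size=32, scale=100.0):
    """A random image with genuine structure: smooth blobs plus a step edge.

    Guaranteed non-constant with localised features, so every metric
    (including the PC-weighted ones) is well defined on it.
    """
    from scipy import ndimage

    smooth = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), 3.0)
    smooth = smooth / max(np.abs(smooth).max(), 1e-12) * scale
    col = int(rng.integers(size // 4, 3 * size // 4))
    step = np.zeros((size, size))
    step[:, col:] = 0.5 * scale
    return smooth + step + rng.normal(0.0, 0.02 * scale, (size, size))


@pytest.fixture
def structured_image(rng):
    return ImageGrid(structured_pixels(rng))
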