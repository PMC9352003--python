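import numpy as np
import pytest

from applegrade.vision import VisionConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def config():
    return VisionConfig()


def draw_disc(shape, center, radius):
    """Boolean disc mask: pixels whose centers lie within radius of center."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


def draw_ellipse(shape, center, semi_x, semi_y):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((xx - center[0]) / semi_x) ** 2 + ((yy - center[1]) / semi_y) ** 2 <= 1.0


def solid_image(shape, rgb):
    img = np.zeros((*shape, 3), dtype=np.uint8)
    img[:] = rgb
    return img
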