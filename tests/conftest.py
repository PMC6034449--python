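import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def random_images(rng):
    """Factory for batches of small random integer images."""

    def make(n, shape=(16, 16), levels=8, seed=None):
        local = np.random.default_rng(seed) if seed is not None else rng
        return [
            local.integers(0, levels, size=shape).astype(np.uint8)
            for _ in range(n)
        ]

    return make


def disk_pixels(radius: int, center=(0, 0)):
    """Rasterized disk: pixel centers within ``radius`` of the center."""
    cy, cx = center
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    mask = yy**2 + xx**2 <= radius**2
    return yy[mask] + cy + radius, xx[mask] + cx + radius
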