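import numpy as np
import pytest

from pcrad.image import BinaryMask, DiscretizedROI, ImageVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_roi(rng, max_side=5, n_levels=4, p_mask=0.7):
    """A random small DiscretizedROI (guaranteed non-empty)."""
    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask.flat[int(rng.integers(mask.size))] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return DiscretizedROI(levels, mask, n_levels)


@pytest.fixture
def roi_factory(rng):
    return lambda **kw: random_roi(rng, **kw)


def digital_ball(radius_vox: int, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    n = 2 * radius_vox + 5
    zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    c = (n - 1) / 2
    mask = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius_vox**2
    return BinaryMask(mask, spacing)


def volume_from(values, spacing=(1.0, 1.0, 1.0)) -> ImageVolume:
    return ImageVolume(np.asarray(values, dtype=float), spacing)
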