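import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from rimshrink.io import CTVolume, LesionMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_blob(rng, shape, p_seed=0.5, smooth_iters=2):
    """A connected-ish random blob mask: thresholded smoothed noise around
    a central seed, guaranteed non-empty."""
    from scipy import ndimage

    field = rng.random(shape)
    field = ndimage.uniform_filter(field, size=3)
    mask = field > np.quantile(field, 0.7)
    centre = tuple(s // 2 for s in shape)
    mask[centre] = True
    lab, _ = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    mask = lab == lab[centre]
    return mask


def ball_mask(shape, spacing, radius_mm, centre_mm=None):
    spacing = np.asarray(spacing, float)
    if centre_mm is None:
        centre_mm = np.asarray(shape) * spacing / 2.0
    coords = [((np.arange(shape[a]) + 0.5) * spacing[a] - centre_mm[a]) for a in range(3)]
    d2 = (coords[0][:, None, None] ** 2 + coords[1][None, :, None] ** 2
          + coords[2][None, None, :] ** 2)
    return d2 <= radius_mm**2


@pytest.fixture
def small_volume_mask(rng):
    """A small random volume with a central blob mask."""
    shape = (12, 12, 8)
    values = rng.normal(20.0, 15.0, size=shape)
    vol = CTVolume(values=values, spacing=(1.0, 1.0, 2.0))
    mask = LesionMask(labels=random_blob(rng, shape))
    return vol, mask
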