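import numpy as np
import pytest

from lesionrad.io import LesionMask, VolumeImage
from lesionrad.preprocessing import DiscretizedROI


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_volume_mask(rng):
    """A noisy 16x16x8 volume with a central box ROI, anisotropic spacing."""
    vals = rng.normal(size=(16, 16, 8))
    mask = np.zeros((16, 16, 8), dtype=bool)
    mask[4:12, 4:12, 2:6] = True
    return VolumeImage(vals, (1.0, 1.0, 5.0)), LesionMask(mask, (1.0, 1.0, 5.0))


def make_discretized(levels, n_levels, spacing=(1.0, 1.0, 1.0), mask=None):
    levels = np.asarray(levels, dtype=np.int32)
    if levels.ndim == 2:
        levels = levels[:, :, None]
    if mask is None:
        mask = levels > 0
    return DiscretizedROI(levels.copy(), np.asarray(mask, bool), n_levels,
                          np.arange(n_levels + 1, dtype=float), spacing)


def random_discretized(rng, shape=(6, 6, 3), n_levels=4, mask_p=0.8):
    """Random small ROI for fuzzing against the brute-force oracles."""
    mask = rng.uniform(size=shape) < mask_p
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    levels = np.zeros(shape, dtype=np.int32)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return make_discretized(levels, n_levels, mask=mask)
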