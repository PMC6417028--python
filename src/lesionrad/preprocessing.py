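"""Intensity normalization and grey-level discretization.

Normalization is the z-score map f(x) = s * (x - mean) / sd computed over
the whole image with the population standard deviation; it is applied to
every sequence volume before both original and filtered feature
extraction.  Discretization uses a fixed number of equal-width bins over
the in-mask intensity range (absolute bin widths are meaningless after
normalization).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .io import LesionMask, VolumeImage, check_aligned


@dataclasses.dataclass
class DiscretizedROI:
    """Integer grey levels (1..n_levels) on the grid; 0 marks background.

    ``n_levels`` is the effective number of levels actually present in the
    configured binning (>= 1); ``degenerate`` flags a constant ROI.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_edges: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("in-mask levels must lie in [1, n_levels]")

    @property
    def degenerate(self) -> bool:
        return self.n_levels < 2


def normalize_intensity(vol: VolumeImage, s: float = 1.0) -> VolumeImage:
    """Z-score normalize a volume: output mean 0, population SD ``s``.

    Raises on constant volumes rather than dividing by zero.
    """
    if s <= 0:
        raise ValueError("scale s must be positive")
    x = vol.values
    mu = x.mean()
    sd = x.std()  # population SD
    if sd == 0:
        raise ValueError("cannot normalize a constant volume (zero spread)")
    return VolumeImage(s * (x - mu) / sd, vol.spacing_mm, vol.sequence_tag, vol.affine)


def discretize(vol: VolumeImage, mask: LesionMask, n_bins: int = 32) -> DiscretizedROI:
    """Equal-width binning of in-mask intensities into ``n_bins`` levels.

    The bins span [min, max] of the in-mask intensities; the maximum value
    maps to the top level.  A constant ROI yields a single-level result
    with a warning (texture features then take their degenerate values).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    check_aligned(vol, mask)
    inside = vol.values[mask.values]
    lo, hi = float(inside.min()), float(inside.max())
    levels = np.zeros(vol.shape, dtype=np.int32)
    if lo == hi:
        warnings.warn("constant ROI: discretization degenerates to a single level")
        levels[mask.values] = 1
        return DiscretizedROI(levels, mask.values.copy(), 1,
                              np.array([lo, hi]), vol.spacing_mm)
    edges = np.linspace(lo, hi, n_bins + 1)
    width = (hi - lo) / n_bins
    binned = np.floor((vol.values - lo) / width).astype(np.int32) + 1
    np.clip(binned, 1, n_bins, out=binned)
    levels[mask.values] = binned[mask.values]
    return DiscretizedROI(levels, mask.values.copy(), n_bins, edges, vol.spacing_mm)
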