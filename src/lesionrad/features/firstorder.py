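"""First-order (histogram) statistics of in-ROI intensities.

All 19 features depend only on the multiset of in-mask intensity values,
never on voxel positions.  Entropy and Uniformity are computed on the
discretized histogram (same equal-width binning as the texture matrices).
"""

from __future__ import annotations

import numpy as np

from ..io import LesionMask, VolumeImage, check_aligned

FIRST_ORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "StandardDeviation",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def _histogram_probs(x: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if lo == hi:
        return np.array([1.0])
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    return counts[counts > 0] / x.size


def first_order_features(vol: VolumeImage, mask: LesionMask,
                         n_bins: int = 32) -> dict[str, float]:
    """Compute the 19 first-order features over the masked voxels."""
    check_aligned(vol, mask)
    x = vol.values[mask.values].astype(np.float64)
    n = x.size
    mean = x.mean()
    var = x.var()  # population variance
    sd = np.sqrt(var)
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])  # linear interpolation
    energy = float(np.sum(x * x))
    probs = _histogram_probs(x, n_bins)
    entropy = float(-np.sum(probs * np.log2(probs)))
    uniformity = float(np.sum(probs * probs))
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    if sd > 0:
        skew = float(np.mean((x - mean) ** 3) / sd**3)
        kurt = float(np.mean((x - mean) ** 4) / var**2)  # non-excess (Pearson)
    else:
        skew = 0.0  # degenerate constant ROI
        kurt = 0.0
    return {
        "Energy": energy,
        "TotalEnergy": energy * vol.voxel_volume_mm3,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(energy / n)),
        "StandardDeviation": float(sd),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": float(var),
        "Uniformity": uniformity,
    }
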