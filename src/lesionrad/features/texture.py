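"""Grey-level texture matrices (GLCM, GLRLM, GLSZM) and their features.

GLCM and GLRLM are computed per direction over the 13 unique 3-D offsets
(26-neighbourhood modulo sign) at distance 1 and the features are averaged
arithmetically over directions; GLSZM is direction-free with 26-connected
zones.  All matrices are restricted to in-mask voxels; grey levels are the
1..Ng output of :func:`lesionrad.preprocessing.discretize` (0 marks
background).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from ..preprocessing import DiscretizedROI

_EPS = np.finfo(np.float64).tiny

#: the 13 unique direction offsets of the 3-D 26-neighbourhood
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

GLCM_NAMES = (
    "Autocorrelation",
    "AverageIntensity",
    "GrayLevelIntensity",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Dissimilarity",
    "Energy",
    "Entropy",
    "Homogeneity1",
    "Homogeneity2",
    "InformalMeasureOfCorrelation1",
    "InformalMeasureOfCorrelation2",
    "InverseDifferenceMoment",
    "InverseDifferenceMomentNormalized",
    "InverseDifference",
    "InverseVariance",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumVariance",
    "SumOfSquares",
)

GLRLM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
)

GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)


@dataclasses.dataclass
class TextureMatrix:
    """A grey-level texture matrix of non-negative counts.

    ``kind`` is one of GLCM/GLRLM/GLSZM; ``offset`` is the direction for
    GLCM/GLRLM (None for GLSZM).  ``counts`` holds raw (unnormalized)
    counts; GLCM counts are already symmetrized.
    """

    kind: str
    counts: np.ndarray
    n_levels: int
    offset: tuple[int, int, int] | None = None

    @property
    def degenerate(self) -> bool:
        return self.counts.sum() == 0

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return self.counts.astype(np.float64)
        return self.counts.astype(np.float64) / total


def _crop_to_mask(d: DiscretizedROI) -> tuple[np.ndarray, np.ndarray]:
    """Crop levels/mask to the mask bounding box (texture is mask-local)."""
    idx = np.argwhere(d.mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return d.levels[sl], d.mask[sl]


def _shift_slices(shape, off):
    """Paired slice tuples (source, destination) for an integer shift."""
    src, dst = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def glcm_matrix(d: DiscretizedROI, offset: tuple[int, int, int],
                distance: int = 1) -> TextureMatrix:
    """Symmetrized co-occurrence counts for one direction offset."""
    if tuple(offset) == (0, 0, 0):
        raise ValueError("GLCM offset must be non-zero")
    off = tuple(int(o) * distance for o in offset)
    levels, _ = _crop_to_mask(d)
    ng = d.n_levels
    src, dst = _shift_slices(levels.shape, off)
    a = levels[src].ravel()
    b = levels[dst].ravel()
    valid = (a > 0) & (b > 0)
    a, b = a[valid] - 1, b[valid] - 1
    mat = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
    mat = mat + mat.T  # symmetrize
    return TextureMatrix("GLCM", mat, ng, tuple(offset))


def _glcm_features_single(mat: TextureMatrix) -> dict[str, float]:
    ng = mat.n_levels
    if mat.degenerate:
        feats = {name: 0.0 for name in GLCM_NAMES}
        feats["Correlation"] = 1.0  # correlation-type degenerate convention
        feats["InformalMeasureOfCorrelation2"] = 1.0
        return feats
    p = mat.normalized()
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sig_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    sig_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))

    # diagonal (difference) and cross-diagonal (sum) marginals
    k_diff = np.arange(ng, dtype=np.float64)           # |i-j| = 0..Ng-1
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int), p)
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)  # i+j = 2..2Ng
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int) - 2, p)

    entropy = float(-np.sum(p * np.log2(p + _EPS)))
    hx = float(-np.sum(px * np.log2(px + _EPS)))
    hy = float(-np.sum(py * np.log2(py + _EPS)))
    pxpy = np.outer(px, py)
    hxy1 = float(-np.sum(p * np.log2(pxpy + _EPS)))
    hxy2 = float(-np.sum(pxpy * np.log2(pxpy + _EPS)))
    imc1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    diff_avg = float(np.sum(k_diff * p_diff))
    sum_avg = float(np.sum(k_sum * p_sum))
    if sig_x * sig_y > 0:
        correlation = float((np.sum(ii * jj * p) - mu_x * mu_y) / (sig_x * sig_y))
    else:
        correlation = 1.0  # constant ROI convention
    off_diag = ii != jj
    inverse_variance = float(np.sum(p[off_diag] / (ii - jj)[off_diag] ** 2))

    return {
        "Autocorrelation": float(np.sum(ii * jj * p)),
        "AverageIntensity": mu_x,  # interpretive mapping: GLCM joint average
        "GrayLevelIntensity": float(np.sum((ii - mu_x) ** 2 * p)),  # joint variance
        "ClusterProminence": float(np.sum((ii + jj - mu_x - mu_y) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - mu_x - mu_y) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - mu_x - mu_y) ** 2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-np.sum(p_diff * np.log2(p_diff + _EPS))),
        "DifferenceVariance": float(np.sum((k_diff - diff_avg) ** 2 * p_diff)),
        "Dissimilarity": float(np.sum(np.abs(ii - jj) * p)),
        "Energy": float(np.sum(p * p)),
        "Entropy": entropy,
        "Homogeneity1": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Homogeneity2": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "InformalMeasureOfCorrelation1": float(imc1),
        "InformalMeasureOfCorrelation2": imc2,
        "InverseDifferenceMoment": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "InverseDifferenceMomentNormalized": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "InverseDifference": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "InverseVariance": inverse_variance,
        "MaximumProbability": float(p.max()),
        "SumAverage": sum_avg,
        "SumEntropy": float(-np.sum(p_sum * np.log2(p_sum + _EPS))),
        "SumVariance": float(np.sum((k_sum - sum_avg) ** 2 * p_sum)),
        "SumOfSquares": float(np.sum((ii - mu_x) ** 2 * p)),
    }


def glcm_features(d: DiscretizedROI, distance: int = 1) -> dict[str, float]:
    """The 27 co-occurrence features averaged over the 13 directions.

    Directions without any in-mask voxel pair (e.g. the out-of-plane
    offsets of a single-slice ROI) are excluded from the average; if no
    direction has pairs the degenerate conventions apply.
    """
    matrices = [glcm_matrix(d, off, distance) for off in DIRECTIONS_13]
    live = [m for m in matrices if not m.degenerate]
    if not live:
        return _glcm_features_single(matrices[0])
    per_dir = [_glcm_features_single(m) for m in live]
    return {name: float(np.mean([f[name] for f in per_dir])) for name in GLCM_NAMES}


def glrlm_matrix(d: DiscretizedROI, offset: tuple[int, int, int]) -> TextureMatrix:
    """Run-length counts (level x run length) along one direction.

    Runs are maximal sequences of equal grey level among in-mask voxels;
    background/out-of-mask voxels break runs.
    """
    if tuple(offset) == (0, 0, 0):
        raise ValueError("GLRLM offset must be non-zero")
    levels, _ = _crop_to_mask(d)
    ng = d.n_levels
    off = np.asarray(offset, dtype=np.int64)
    shape = np.asarray(levels.shape)

    # run starts: in-mask voxels whose predecessor along -offset is not the
    # same grey level (or falls outside the grid / the mask)
    same_prev = np.zeros(levels.shape, dtype=bool)
    src, dst = _shift_slices(levels.shape, tuple(off))
    same_prev[dst] = (levels[dst] == levels[src]) & (levels[src] > 0)
    starts = np.argwhere((levels > 0) & ~same_prev)

    run_level = levels[tuple(starts.T)]
    run_len = np.ones(len(starts), dtype=np.int64)
    pos = starts.copy()
    active = np.arange(len(starts))
    while active.size:
        nxt = pos[active] + off
        inside = np.all((nxt >= 0) & (nxt < shape), axis=1)
        cont = np.zeros(active.size, dtype=bool)
        if inside.any():
            vals = levels[tuple(nxt[inside].T)]
            cont[inside] = vals == run_level[active[inside]]
        run_len[active[cont]] += 1
        pos[active[cont]] = nxt[cont]
        active = active[cont]

    max_len = int(run_len.max()) if len(run_len) else 1
    mat = np.zeros((ng, max_len), dtype=np.float64)
    np.add.at(mat, (run_level - 1, run_len - 1), 1.0)
    return TextureMatrix("GLRLM", mat, ng, tuple(offset))


def _glrlm_features_single(mat: TextureMatrix, n_voxels: int) -> dict[str, float]:
    if mat.degenerate:
        return {name: 0.0 for name in GLRLM_NAMES}
    counts = mat.counts
    nr = counts.sum()
    ng, max_len = counts.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, max_len + 1, dtype=np.float64)[None, :]
    p = counts / nr
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    return {
        "GrayLevelNonUniformity": float(np.sum(counts.sum(axis=1) ** 2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(counts.sum(axis=1) ** 2) / nr**2),
        "GrayLevelVariance": float(np.sum((i - mu_i) ** 2 * p)),
        "HighGrayLevelRunEmphasis": float(np.sum(counts * i**2) / nr),
        "LongRunEmphasis": float(np.sum(counts * j**2) / nr),
        "LongRunHighGrayLevelEmphasis": float(np.sum(counts * i**2 * j**2) / nr),
        "LongRunLowGrayLevelEmphasis": float(np.sum(counts * j**2 / i**2) / nr),
        "LowGrayLevelRunEmphasis": float(np.sum(counts / i**2) / nr),
        "ShortRunEmphasis": float(np.sum(counts / j**2) / nr),
        "ShortRunHighGrayLevelEmphasis": float(np.sum(counts * i**2 / j**2) / nr),
        "ShortRunLowGrayLevelEmphasis": float(np.sum(counts / (i**2 * j**2)) / nr),
        "RunEntropy": float(-np.sum(p * np.log2(p + _EPS))),
        "RunLengthNonUniformity": float(np.sum(counts.sum(axis=0) ** 2) / nr),
        "RunLengthNonUniformityNormalized": float(np.sum(counts.sum(axis=0) ** 2) / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "RunVariance": float(np.sum((j - mu_j) ** 2 * p)),
    }


def glrlm_features(d: DiscretizedROI) -> dict[str, float]:
    """The 16 run-length features averaged over the 13 directions.

    A non-empty mask always yields runs in every direction, so no
    degenerate-direction exclusion is needed here.
    """
    n_vox = int(d.mask.sum())
    per_dir = [_glrlm_features_single(glrlm_matrix(d, off), n_vox)
               for off in DIRECTIONS_13]
    return {name: float(np.mean([f[name] for f in per_dir])) for name in GLRLM_NAMES}


def glszm_matrix(d: DiscretizedROI) -> TextureMatrix:
    """Size-zone counts: 26-connected components of equal grey level."""
    levels, mask = _crop_to_mask(d)
    ng = d.n_levels
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    zones: list[tuple[int, int]] = []  # (level, size)
    for g in range(1, ng + 1):
        lab, n = ndimage.label(levels == g, structure=structure)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((g, int(s)) for s in sizes)
    if not zones:
        return TextureMatrix("GLSZM", np.zeros((ng, 1)), ng, None)
    max_size = max(s for _, s in zones)
    mat = np.zeros((ng, max_size), dtype=np.float64)
    for g, s in zones:
        mat[g - 1, s - 1] += 1.0
    return TextureMatrix("GLSZM", mat, ng, None)


def glszm_features(d: DiscretizedROI) -> dict[str, float]:
    """The 16 size-zone features (single direction-free matrix)."""
    mat = glszm_matrix(d)
    n_vox = int(d.mask.sum())
    if mat.degenerate:
        return {name: 0.0 for name in GLSZM_NAMES}
    counts = mat.counts
    nz = counts.sum()
    ng, max_size = counts.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    s = np.arange(1, max_size + 1, dtype=np.float64)[None, :]
    p = counts / nz
    mu_i = float(np.sum(i * p))
    mu_s = float(np.sum(s * p))
    return {
        "SmallAreaEmphasis": float(np.sum(counts / s**2) / nz),
        "LargeAreaEmphasis": float(np.sum(counts * s**2) / nz),
        "GrayLevelNonUniformity": float(np.sum(counts.sum(axis=1) ** 2) / nz),
        "GrayLevelNonUniformityNormalized": float(np.sum(counts.sum(axis=1) ** 2) / nz**2),
        "SizeZoneNonUniformity": float(np.sum(counts.sum(axis=0) ** 2) / nz),
        "SizeZoneNonUniformityNormalized": float(np.sum(counts.sum(axis=0) ** 2) / nz**2),
        "ZonePercentage": float(nz / n_vox),
        "GrayLevelVariance": float(np.sum((i - mu_i) ** 2 * p)),
        "ZoneVariance": float(np.sum((s - mu_s) ** 2 * p)),
        "ZoneEntropy": float(-np.sum(p * np.log2(p + _EPS))),
        "LowGrayLevelZoneEmphasis": float(np.sum(counts / i**2) / nz),
        "HighGrayLevelZoneEmphasis": float(np.sum(counts * i**2) / nz),
        "SmallAreaLowGrayLevelEmphasis": float(np.sum(counts / (i**2 * s**2)) / nz),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(counts * i**2 / s**2) / nz),
        "LargeAreaLowGrayLevelEmphasis": float(np.sum(counts * s**2 / i**2) / nz),
        "LargeAreaHighGrayLevelEmphasis": float(np.sum(counts * i**2 * s**2) / nz),
    }
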