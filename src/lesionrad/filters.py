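"""Filtered image variants feeding the higher-order feature bank.

Twelve variants per volume: four sign-preserving pointwise maps
(exponential, square, squareroot, logarithm) rescaled to the input
magnitude range, plus the eight single-level 3-D wavelet bands of an
undecimated (stationary) Coiflet-1 transform, so the lesion mask applies
to every variant unchanged.  Band letters follow axis order (x, y, z).

Each of the 12 variants contributes the 78 intensity-dependent features
(shape excluded; the mask is unaffected by filtering): 12 x 78 = 936
higher-order features, and 93 + 936 = 1029 in total.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage

from .features import ORIGINAL_FEATURE_COUNT, extract_original, intensity_features
from .io import LesionMask, VolumeImage, check_aligned

POINTWISE_KINDS = ("exponential", "square", "squareroot", "logarithm")
WAVELET_BAND_NAMES = tuple(
    "wavelet-" + "".join(b) for b in itertools.product("LH", repeat=3)
)  # LLL, LLH, LHL, LHH, HLL, HLH, HHL, HHH
FILTER_NAMES = POINTWISE_KINDS + WAVELET_BAND_NAMES  # 12 variants

HIGHER_ORDER_FEATURE_COUNT = 936  # 12 filters x 78 intensity features
TOTAL_FEATURE_COUNT = ORIGINAL_FEATURE_COUNT + HIGHER_ORDER_FEATURE_COUNT  # 1029

# Coiflet-1 analysis filters (orthonormal pair; highpass is the QMF mirror)
_COIF1_LO = np.array([
    -0.015655728135465
    , -0.072732619512854,
    0.384864846864203,
    0.852572020212255,
    0.337897662457809,
    -0.072732619512854,
])
_COIF1_HI = np.array([(-1) ** k * _COIF1_LO[len(_COIF1_LO) - 1 - k]
                      for k in range(len(_COIF1_LO))])


def apply_pointwise_filter(vol: VolumeImage, kind: str) -> VolumeImage:
    """Sign-preserving monotone intensity map rescaled to the input range.

    With M = max|x| over the volume, each map sends 0 -> 0 and +/-M -> +/-M:

    * square:      sign(x) * x^2 / M
    * squareroot:  sign(x) * sqrt(|x| * M)
    * logarithm:   sign(x) * M * ln(|x| + 1) / ln(M + 1)
    * exponential: sign(x) * ((M + 1)^(|x|/M) - 1)
    """
    if kind not in POINTWISE_KINDS:
        raise ValueError(f"unknown pointwise filter {kind!r}")
    x = vol.values
    m = float(np.abs(x).max())
    if m == 0:
        raise ValueError("pointwise filter undefined for an all-zero volume")
    sign = np.sign(x)
    ax = np.abs(x)
    if kind == "square":
        out = sign * ax**2 / m
    elif kind == "squareroot":
        out = sign * np.sqrt(ax * m)
    elif kind == "logarithm":
        out = sign * m * np.log1p(ax) / np.log1p(m)
    else:  # exponential
        out = sign * (np.power(m + 1.0, ax / m) - 1.0)
    return VolumeImage(out, vol.spacing_mm, vol.sequence_tag, vol.affine)


def _filter_axis(data: np.ndarray, filt: np.ndarray, axis: int) -> np.ndarray:
    # periodic boundary; 1/sqrt(2) rescaling keeps the undecimated lowpass
    # branch mean-preserving (LLL of a constant is that constant)
    return ndimage.convolve1d(data, filt / np.sqrt(2.0), axis=axis, mode="wrap")


def wavelet_bands(vol: VolumeImage) -> dict[str, VolumeImage]:
    """Single-level undecimated 3-D Coiflet-1 bands on the original grid."""
    if min(vol.shape) < len(_COIF1_LO):
        raise ValueError(
            f"volume shape {vol.shape} smaller than wavelet filter support "
            f"({len(_COIF1_LO)})"
        )
    bands: dict[str, VolumeImage] = {}
    for letters in itertools.product("LH", repeat=3):
        data = vol.values
        for axis, letter in enumerate(letters):
            filt = _COIF1_LO if letter == "L" else _COIF1_HI
            data = _filter_axis(data, filt, axis)
        bands["wavelet-" + "".join(letters)] = VolumeImage(
            data, vol.spacing_mm, vol.sequence_tag, vol.affine)
    return bands


def dwt3_decimated(values: np.ndarray) -> dict[str, np.ndarray]:
    """Orthonormal decimated single-level 3-D transform (periodic).

    Provided for verification: on dyadic grids the band energies sum to the
    input energy (Parseval).  The feature bank uses the undecimated variant.
    """
    if any(n % 2 for n in values.shape):
        raise ValueError("decimated transform requires even axis lengths")

    def analyze(data: np.ndarray, filt: np.ndarray, axis: int) -> np.ndarray:
        n = data.shape[axis]
        data = np.moveaxis(data, axis, -1)
        idx = (np.arange(0, n, 2)[:, None] + np.arange(len(filt))[None, :]) % n
        out = np.tensordot(data[..., idx], filt, axes=([-1], [0]))
        return np.moveaxis(out, -1, axis)

    bands: dict[str, np.ndarray] = {}
    for letters in itertools.product("LH", repeat=3):
        data = values
        for axis, letter in enumerate(letters):
            filt = _COIF1_LO if letter == "L" else _COIF1_HI
            data = analyze(data, filt, axis)
        bands["".join(letters)] = data
    return bands


def filter_bank(vol: VolumeImage) -> dict[str, VolumeImage]:
    """All 12 filtered variants of a volume, keyed by filter name."""
    out = {kind: apply_pointwise_filter(vol, kind) for kind in POINTWISE_KINDS}
    out.update(wavelet_bands(vol))
    assert len(out) == 12
    return out


def extract_higher_order(vol: VolumeImage, mask: LesionMask,
                         n_bins: int = 32) -> dict[str, float]:
    """The 936 filtered-image features, names prefixed by filter name."""
    check_aligned(vol, mask)
    out: dict[str, float] = {}
    for name, filtered in filter_bank(vol).items():
        feats = intensity_features(filtered, mask, n_bins=n_bins)
        out.update({f"{name}::{k}": v for k, v in feats.items()})
    assert len(out) == HIGHER_ORDER_FEATURE_COUNT
    return out


def extract_all(vol: VolumeImage, mask: LesionMask,
                n_bins: int = 32) -> dict[str, float]:
    """All 1029 features of one volume/mask pair: original + higher-order.

    Original features get the ``original::`` prefix so every name states
    its filter variant.
    """
    out = {f"original::{k}": v
           for k, v in extract_original(vol, mask, n_bins=n_bins).items()}
    out.update(extract_higher_order(vol, mask, n_bins=n_bins))
    assert len(out) == TOTAL_FEATURE_COUNT
    return out
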