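"""Original-image radiomics features: 19 first-order + 15 shape + 27 GLCM
+ 16 GLRLM + 16 GLSZM = 93 named values per volume/mask pair."""

from __future__ import annotations

import numpy as np

from ..io import LesionMask, VolumeImage, check_aligned
from ..preprocessing import DiscretizedROI, discretize
from .firstorder import FIRST_ORDER_NAMES, first_order_features
from .registry import FEATURE_REGISTRY, ORIGINAL_FEATURE_COUNT, registry_counts, registry_json
from .shape import SHAPE_NAMES, shape_features
from .texture import (
    DIRECTIONS_13,
    GLCM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    TextureMatrix,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
)

__all__ = [
    "DIRECTIONS_13",
    "FEATURE_REGISTRY",
    "FIRST_ORDER_NAMES",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "ORIGINAL_FEATURE_COUNT",
    "SHAPE_NAMES",
    "TextureMatrix",
    "extract_original",
    "intensity_features",
    "first_order_features",
    "glcm_features",
    "glcm_matrix",
    "glrlm_features",
    "glrlm_matrix",
    "glszm_features",
    "glszm_matrix",
    "registry_counts",
    "registry_json",
    "shape_features",
]


def intensity_features(vol: VolumeImage, mask: LesionMask,
                       n_bins: int = 32) -> dict[str, float]:
    """The 78 intensity-dependent features (everything except shape).

    This is the per-filtered-image basis of the higher-order bank:
    19 first-order + 27 GLCM + 16 GLRLM + 16 GLSZM.
    """
    check_aligned(vol, mask)
    disc = discretize(vol, mask, n_bins=n_bins)
    out: dict[str, float] = {}
    out.update({f"firstorder::{k}": v
                for k, v in first_order_features(vol, mask, n_bins).items()})
    out.update({f"glcm::{k}": v for k, v in glcm_features(disc).items()})
    out.update({f"glrlm::{k}": v for k, v in glrlm_features(disc).items()})
    out.update({f"glszm::{k}": v for k, v in glszm_features(disc).items()})
    return out


def extract_original(vol: VolumeImage, mask: LesionMask,
                     n_bins: int = 32) -> dict[str, float]:
    """All 93 original-image features in deterministic registry order."""
    check_aligned(vol, mask)
    out = intensity_features(vol, mask, n_bins)
    out.update({f"shape::{k}": v
                for k, v in shape_features(mask, vol.spacing_mm).items()})
    ordered = {}
    for entry in FEATURE_REGISTRY:
        key = f"{entry['class']}::{entry['name']}"
        ordered[key] = out[key]
    assert len(ordered) == ORIGINAL_FEATURE_COUNT
    if not all(np.isfinite(v) for v in ordered.values()):
        bad = [k for k, v in ordered.items() if not np.isfinite(v)]
        raise ValueError(f"non-finite feature values: {bad}")
    return ordered
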