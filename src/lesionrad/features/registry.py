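"""Machine-readable registry of the 93 original feature definitions.

Each entry records the feature name, its class, and a short formula note.
Two co-occurrence names carry nonstandard labels whose intended formulas
are not documented anywhere authoritative; their mappings are interpretive
and flagged below:

* ``AverageIntensity`` -> GLCM joint average mu = sum_i,j i * p(i, j)
* ``GrayLevelIntensity`` -> GLCM joint grey-level variance
  sum_i,j (i - mu)^2 * p(i, j)

``Homogeneity1``/``InverseDifference`` and
``Homogeneity2``/``InverseDifferenceMoment`` are distinct registry entries
whose standard formulas coincide; both pairs are kept because the feature
bank enumerates them separately.
"""

from __future__ import annotations

import json

from .firstorder import FIRST_ORDER_NAMES
from .shape import SHAPE_NAMES
from .texture import GLCM_NAMES, GLRLM_NAMES, GLSZM_NAMES

FEATURE_CLASSES = ("firstorder", "shape", "glcm", "glrlm", "glszm")

_FORMULA_NOTES = {
    ("glcm", "AverageIntensity"): "interpretive: joint average sum i*p(i,j)",
    ("glcm", "GrayLevelIntensity"): "interpretive: joint variance sum (i-mu)^2 p(i,j)",
    ("glcm", "InverseDifference"): "sum p/(1+|i-j|); coincides with Homogeneity1",
    ("glcm", "InverseDifferenceMoment"): "sum p/(1+(i-j)^2); coincides with Homogeneity2",
    ("glszm", "GrayLevelNonUniformityNormalized"):
        "listed with a truncated label in the source taxonomy",
}


def _entries():
    groups = {
        "firstorder": FIRST_ORDER_NAMES,
        "shape": SHAPE_NAMES,
        "glcm": GLCM_NAMES,
        "glrlm": GLRLM_NAMES,
        "glszm": GLSZM_NAMES,
    }
    entries = []
    for cls, names in groups.items():
        for name in names:
            entries.append({
                "name": name,
                "class": cls,
                "formula_id": f"{cls}.{name}",
                "note": _FORMULA_NOTES.get((cls, name), "standard definition"),
            })
    return entries


FEATURE_REGISTRY: tuple[dict, ...] = tuple(_entries())

ORIGINAL_FEATURE_COUNT = len(FEATURE_REGISTRY)  # 93


def registry_counts() -> dict[str, int]:
    counts: dict[str, int] = {}
    for entry in FEATURE_REGISTRY:
        counts[entry["class"]] = counts.get(entry["class"], 0) + 1
    return counts


def registry_json() -> str:
    return json.dumps(list(FEATURE_REGISTRY), indent=2)
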