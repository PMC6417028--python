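"""Schema-validated pipeline configuration (YAML).

Unknown keys are rejected at load time; the full config is serialized
into every output artifact as a provenance block.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .synthetic import ClassEffect, PhantomSpec


@dataclasses.dataclass
class PreprocessingConfig:
    normalize_scale: float = 1.0
    n_bins: int = 32

    def __post_init__(self) -> None:
        if self.normalize_scale <= 0:
            raise ValueError("normalize.scale must be positive")
        if self.n_bins < 2:
            raise ValueError("discretize.n_bins must be >= 2")


@dataclasses.dataclass
class SelectionConfig:
    variance_threshold: float = 0.8
    univariate_alpha: float = 0.05
    alpha_min: float = 1e-4
    alpha_max: float = 10 ** 0.5
    alpha_num: int = 60
    cv_folds: int = 5

    def alpha_grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.alpha_min), np.log10(self.alpha_max),
                           self.alpha_num)


@dataclasses.dataclass
class SplitConfig:
    test_fraction: float = 0.2
    grouping: str = "subject"

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("split.test_fraction must be in (0, 1)")
        if self.grouping not in ("subject", "lesion"):
            raise ValueError("split.grouping must be 'subject' or 'lesion'")


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    phantom: PhantomSpec = dataclasses.field(default_factory=PhantomSpec)
    preprocessing: PreprocessingConfig = dataclasses.field(
        default_factory=PreprocessingConfig)
    selection: SelectionConfig = dataclasses.field(default_factory=SelectionConfig)
    split: SplitConfig = dataclasses.field(default_factory=SplitConfig)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def _build(cls, data: dict, context: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown config keys under {context}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None = None,
                data: dict | None = None) -> PipelineConfig:
    """Load and validate a pipeline config from YAML (or a dict)."""
    if data is None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_fields
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    phantom_data = dict(data.get("phantom", {}))
    if "class_effects" in phantom_data:
        phantom_data["class_effects"] = {
            seq: _build(ClassEffect, dict(eff), f"phantom.class_effects.{seq}")
            for seq, eff in phantom_data["class_effects"].items()}
    for tup_key in ("lesions_per_subject_range", "grid_shape", "spacing_mm",
                    "lesion_radius_range_mm"):
        if tup_key in phantom_data:
            phantom_data[tup_key] = tuple(phantom_data[tup_key])
    return PipelineConfig(
        seed=int(data.get("seed", 0)),
        phantom=_build(PhantomSpec, phantom_data, "phantom"),
        preprocessing=_build(PreprocessingConfig,
                             dict(data.get("preprocessing", {})), "preprocessing"),
        selection=_build(SelectionConfig, dict(data.get("selection", {})),
                         "selection"),
        split=_build(SplitConfig, dict(data.get("split", {})), "split"),
    )
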