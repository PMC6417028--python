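"""Reproducible two-class multi-sequence lesion phantoms.

Every lesion is an ellipsoid (optionally lobulated by a fused satellite
ellipsoid) planted in a Gaussian-noise background over a smooth bias
field.  Class-1 lesions additionally receive per-sequence mean shifts (in
units of the background noise SD) and a multiplicative heterogeneity
texture: a Gaussian random field smoothed at ~2-voxel scale whose in-mask
amplitude is ``noise_sd * (heterogeneity - 1)``, so a multiplier of 1
means no class difference and larger multipliers strictly increase
within-mask variance.

The generator also provides planted-effect *feature tables* (tabular
cohorts with known informative features) used to validate the selection
cascade and classifiers at scale without paying image-extraction cost.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import (
    SEQUENCE_TAGS,
    FeatureTable,
    LesionMask,
    VolumeImage,
    write_mask,
    write_volume,
)

MANIFEST_COLUMNS = ("subject_id", "lesion_id", "label",
                    "inphase", "outphase", "t2wi", "dwi", "mask")


@dataclasses.dataclass
class ClassEffect:
    """Class-1 deviation for one sequence.

    ``mean_shift`` is in units of the background noise SD;
    ``heterogeneity`` is a multiplicative texture knob with 1 = none.
    """

    mean_shift: float = 0.0
    heterogeneity: float = 1.0

    def __post_init__(self) -> None:
        if self.heterogeneity < 1.0:
            raise ValueError("heterogeneity multiplier must be >= 1")


def default_class_effects() -> dict[str, ClassEffect]:
    # class 0 is homogeneous and T2-bright; class 1 is heterogeneous with
    # planted first-order shifts on every sequence
    return {
        "inphase": ClassEffect(mean_shift=1.0, heterogeneity=2.5),
        "outphase": ClassEffect(mean_shift=-1.5, heterogeneity=2.5),
        "t2wi": ClassEffect(mean_shift=-2.0, heterogeneity=2.5),
        "dwi": ClassEffect(mean_shift=1.5, heterogeneity=2.5),
    }


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of a synthetic two-class lesion cohort."""

    n_subjects: int = 30
    lesions_per_subject_range: tuple[int, int] = (1, 3)
    class_balance: float = 0.5
    grid_shape: tuple[int, int, int] = (40, 40, 16)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 5.0)
    lesion_radius_range_mm: tuple[float, float] = (8.0, 14.0)
    class_effects: dict[str, ClassEffect] = dataclasses.field(
        default_factory=default_class_effects)
    noise_sd: float = 1.0
    lesion_contrast: float = 3.0  # base in-lesion signal, both classes
    lobulated_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be strictly between 0 and 1")
        lo, hi = self.lesions_per_subject_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid lesions_per_subject_range")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid too small (each axis must be >= 8 voxels)")
        rlo, rhi = self.lesion_radius_range_mm
        if not 0 < rlo <= rhi:
            raise ValueError("lesion radii must be positive")
        extent = np.asarray(self.grid_shape) * np.asarray(self.spacing_mm)
        if rhi >= extent.min() / 2:
            raise ValueError(
                f"lesion radius {rhi} mm does not fit the grid "
                f"(half extent {extent.min() / 2} mm)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        unknown = set(self.class_effects) - set(SEQUENCE_TAGS)
        if unknown:
            raise ValueError(f"class_effects for unknown sequences: {sorted(unknown)}")


def _ellipsoid(coords_mm: np.ndarray, center: np.ndarray,
               radii: np.ndarray) -> np.ndarray:
    d = (coords_mm - center) / radii
    return (d * d).sum(axis=-1) <= 1.0


def _smooth_field(rng: np.random.Generator, shape, sigma_vox=2.0) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    return field / field.std()


def generate_lesion(spec: PhantomSpec, class_label: int,
                    rng: np.random.Generator
                    ) -> tuple[dict[str, VolumeImage], LesionMask]:
    """One lesion: four co-registered sequence volumes and a binary mask."""
    if class_label not in (0, 1):
        raise ValueError("class_label must be 0 or 1")
    shape = tuple(spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm)
    extent = np.asarray(shape) * spacing
    grids = np.meshgrid(*[(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)],
                        indexing="ij")
    coords = np.stack(grids, axis=-1)

    rlo, rhi = spec.lesion_radius_range_mm
    radii = rng.uniform(rlo, rhi, size=3)
    # keep the whole lesion inside the grid
    center = np.array([rng.uniform(r + 1.0, e - r - 1.0)
                       for r, e in zip(radii, extent)])
    mask_arr = _ellipsoid(coords, center, radii)
    if rng.uniform() < spec.lobulated_fraction:
        # fused satellite lobe: overlapping, so connectivity is preserved
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        off = center + direction * radii * 0.6
        lobe_radii = radii * rng.uniform(0.4, 0.7)
        lobe = _ellipsoid(coords, off, lobe_radii)
        mask_arr |= lobe
        mask_arr &= _ellipsoid(coords, center, radii * 1.6)  # stay in bounds
    if mask_arr.sum() < 27:
        raise ValueError(
            "degenerate spec: lesion smaller than 27 voxels at this spacing; "
            "increase lesion_radius_range_mm or reduce spacing")

    effects = {tag: spec.class_effects.get(tag, ClassEffect())
               for tag in SEQUENCE_TAGS}
    volumes: dict[str, VolumeImage] = {}
    for tag in SEQUENCE_TAGS:
        bias = 0.5 * spec.noise_sd * _smooth_field(rng, shape, sigma_vox=6.0)
        background = bias + spec.noise_sd * rng.standard_normal(shape)
        signal = background
        signal = signal + mask_arr * spec.lesion_contrast * spec.noise_sd
        eff = effects[tag]
        if class_label == 1:
            signal = signal + mask_arr * eff.mean_shift * spec.noise_sd
            if eff.heterogeneity > 1.0:
                texture = _smooth_field(rng, shape, sigma_vox=2.0)
                amp = spec.noise_sd * (eff.heterogeneity - 1.0)
                signal = signal + mask_arr * amp * texture
        volumes[tag] = VolumeImage(signal, tuple(spec.spacing_mm), tag)
    mask = LesionMask(mask_arr, tuple(spec.spacing_mm))
    return volumes, mask


@dataclasses.dataclass
class CohortManifest:
    """Rows of (subject, lesion, label, 4 volume paths, mask path)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(MANIFEST_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"manifest is missing columns: {sorted(missing)}")
        if self.frame["lesion_id"].duplicated().any():
            raise ValueError("lesion_ids must be unique")
        labels = set(self.frame["label"].unique())
        if not labels <= {0, 1}:
            raise ValueError(f"labels must be binary 0/1, got {sorted(labels)}")
        self.frame = self.frame.loc[:, list(MANIFEST_COLUMNS)].reset_index(drop=True)

    @property
    def n_lesions(self) -> int:
        return len(self.frame)

    def save(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "CohortManifest":
        return cls(pd.read_csv(path))


def cohort_plan(spec: PhantomSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Subject-level plan: one row of (subject_id, label, n_lesions) each.

    Class labels are drawn per subject (all lesions of one subject share a
    class), so subject-grouped splits remain class-stratifiable.
    """
    lo, hi = spec.lesions_per_subject_range
    labels = (rng.uniform(size=spec.n_subjects) < spec.class_balance).astype(int)
    n_lesions = rng.integers(lo, hi + 1, size=spec.n_subjects)
    return pd.DataFrame({
        "subject_id": [f"sub{si:04d}" for si in range(spec.n_subjects)],
        "label": labels,
        "n_lesions": n_lesions,
    })


def generate_cohort(spec: PhantomSpec, out_dir: str | Path) -> CohortManifest:
    """Write NIfTI volumes/masks for a full cohort plus a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    plan = cohort_plan(spec, rng)
    rows = []
    for rec in plan.itertuples():
        subject_id = rec.subject_id
        label = int(rec.label)
        for li in range(int(rec.n_lesions)):
            lesion_id = f"{subject_id}_les{li:02d}"
            volumes, mask = generate_lesion(spec, label, rng)
            row = {"subject_id": subject_id, "lesion_id": lesion_id, "label": label}
            try:
                for tag, vol in volumes.items():
                    path = out_dir / f"{lesion_id}_{tag}.nii.gz"
                    write_volume(vol, path)
                    row[tag] = str(path)
                mask_path = out_dir / f"{lesion_id}_mask.nii.gz"
                write_mask(mask, mask_path)
                row["mask"] = str(mask_path)
            except OSError as exc:
                raise OSError(f"failed writing cohort files under {out_dir}: {exc}") from exc
            rows.append(row)
    manifest = CohortManifest(pd.DataFrame(rows))
    manifest.save(out_dir / "manifest.csv")
    return manifest


def null_spec(**overrides) -> PhantomSpec:
    """A spec with no class-separating structure (null calibration)."""
    effects = {tag: ClassEffect(0.0, 1.0) for tag in SEQUENCE_TAGS}
    kwargs = dict(class_effects=effects)
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def planted_feature_table(n_lesions: int = 200,
                          n_informative: int = 3,
                          n_noise: int = 97,
                          effect: float = 2.0,
                          sequences: tuple[str, ...] = SEQUENCE_TAGS,
                          lesions_per_subject_range: tuple[int, int] = (1, 1),
                          seed: int = 0) -> tuple[FeatureTable, list[str]]:
    """Tabular cohort with known informative features per sequence.

    Informative features are standard normal plus ``effect`` for class-1
    lesions (standardized effect size = ``effect``); noise features are
    pure standard normal.  Returns the table and the ground-truth
    informative column names.
    """
    rng = np.random.default_rng(seed)
    lo, hi = lesions_per_subject_range
    subjects, labels = [], []
    si = 0
    while len(labels) < n_lesions:
        n_les = int(rng.integers(lo, hi + 1))
        label = int(rng.uniform() < 0.5)
        for _ in range(min(n_les, n_lesions - len(labels))):
            subjects.append(f"sub{si:04d}")
            labels.append(label)
        si += 1
    labels_arr = np.asarray(labels)

    data = {"subject_id": subjects,
            "lesion_id": [f"les{i:04d}" for i in range(n_lesions)],
            "label": labels_arr}
    truth: list[str] = []
    for seq in sequences:
        for k in range(n_informative):
            name = f"{seq}::planted::signal::f{k}"
            data[name] = rng.standard_normal(n_lesions) + effect * labels_arr
            truth.append(name)
        for k in range(n_noise):
            data[f"{seq}::planted::noise::f{k}"] = rng.standard_normal(n_lesions)
    return FeatureTable(pd.DataFrame(data)), truth
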