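"""Volume/mask/feature-table I/O with strict alignment validation.

Images are NIfTI (via nibabel); feature tables are CSV with
sequence-qualified column names such as ``t2wi::original::glcm::Contrast``.
Voxel indexing is 0-based and features depend on physical spacing only,
never on origin.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

SEQUENCE_TAGS = ("inphase", "outphase", "t2wi", "dwi")

#: reserved (non-feature) columns of a feature table
META_COLUMNS = ("subject_id", "lesion_id", "label")


class AlignmentError(ValueError):
    """Raised when a mask and a volume do not share grid/spacing."""


@dataclasses.dataclass
class VolumeImage:
    """A 3-D scalar grid with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Finite voxel intensities.
    spacing_mm : tuple of 3 floats
        Physical voxel spacing along each axis, all positive.
    sequence_tag : str or None
        One of ``inphase/outphase/t2wi/dwi`` when known.
    affine : ndarray or None
        Origin/orientation metadata, passed through opaquely.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    sequence_tag: str | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("volume must be a non-empty 3-D grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite voxels")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be 3 positive values")
        if self.sequence_tag is not None and self.sequence_tag not in SEQUENCE_TAGS:
            raise ValueError(f"unknown sequence tag {self.sequence_tag!r}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclasses.dataclass
class LesionMask:
    """A binary 3-D grid aligned to a :class:`VolumeImage`."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3 or arr.size == 0:
            raise ValueError("mask must be a non-empty 3-D grid")
        uniq = np.unique(arr[np.isfinite(arr.astype(np.float64))])
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask must be strictly binary (0/1); multi-label masks are rejected")
        self.values = arr.astype(bool)
        if not self.values.any():
            raise ValueError("empty mask: no foreground voxels")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be 3 positive values")

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def check_aligned(vol: VolumeImage, mask: LesionMask) -> None:
    """Fail loudly if mask and volume differ in grid shape or spacing.

    There is deliberately no silent resampling anywhere in the pipeline.
    """
    if vol.shape != mask.shape:
        raise AlignmentError(
            f"mask shape {mask.shape} does not match volume shape {vol.shape}"
        )
    if not np.allclose(vol.spacing_mm, mask.spacing_mm, rtol=1e-6, atol=0):
        raise AlignmentError(
            f"mask spacing {mask.spacing_mm} does not match volume spacing {vol.spacing_mm}"
        )


def _spacing_from_header(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_volume(path: str | Path, sequence_tag: str | None = None) -> VolumeImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D NIfTI, got {data.ndim}-D: {path}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"volume contains NaN/Inf voxels: {path}")
    return VolumeImage(data, _spacing_from_header(img), sequence_tag, np.asarray(img.affine))


def read_mask(path: str | Path) -> LesionMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D NIfTI mask, got {data.ndim}-D: {path}")
    binary = data > 0.5
    if not binary.any():
        raise ValueError(f"empty mask: {path}")
    return LesionMask(binary, _spacing_from_header(img), np.asarray(img.affine))


def _affine_from_spacing(spacing_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    return aff


def write_volume(vol: VolumeImage, path: str | Path) -> None:
    aff = vol.affine if vol.affine is not None else _affine_from_spacing(vol.spacing_mm)
    img = nib.Nifti1Image(vol.values.astype(np.float64), aff)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))


def write_mask(mask: LesionMask, path: str | Path) -> None:
    aff = mask.affine if mask.affine is not None else _affine_from_spacing(mask.spacing_mm)
    img = nib.Nifti1Image(mask.values.astype(np.uint8), aff)
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))


class FeatureTable:
    """Lesions x named-features matrix with class labels.

    Backed by a pandas DataFrame whose first columns are
    ``subject_id, lesion_id, label`` followed by uniquely named,
    sequence-qualified feature columns.
    """

    def __init__(self, frame: pd.DataFrame):
        for col in META_COLUMNS:
            if col not in frame.columns:
                raise ValueError(f"feature table is missing required column {col!r}")
        feature_cols = [c for c in frame.columns if c not in META_COLUMNS]
        if len(set(feature_cols)) != len(feature_cols):
            dupes = sorted({c for c in feature_cols if feature_cols.count(c) > 1})
            raise ValueError(f"duplicate feature columns: {dupes}")
        ordered = list(META_COLUMNS) + feature_cols
        self.frame = frame.loc[:, ordered].reset_index(drop=True)

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in META_COLUMNS]

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    @property
    def subjects(self) -> np.ndarray:
        return self.frame["subject_id"].to_numpy()

    @property
    def n_lesions(self) -> int:
        return len(self.frame)

    def values(self, names: list[str] | None = None) -> np.ndarray:
        names = self.feature_names if names is None else names
        return self.frame.loc[:, names].to_numpy(dtype=np.float64)

    def subset_rows(self, index) -> "FeatureTable":
        return FeatureTable(self.frame.iloc[np.asarray(index)].reset_index(drop=True))

    def sequence_columns(self, sequence_tag: str) -> list[str]:
        prefix = f"{sequence_tag}::"
        return [c for c in self.feature_names if c.startswith(prefix)]

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, FeatureTable) and self.frame.equals(other.frame)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    # repr-style float formatting keeps >= 12 significant digits through CSV
    table.frame.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    frame = pd.read_csv(path)
    return FeatureTable(frame)
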