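"""Reading and writing the pipeline's on-disk formats.

Volumes and region-of-interest masks travel as NIfTI-1 (``.nii`` /
``.nii.gz``); cohort manifests and feature tables as CSV.  All
geometric consistency checks between a volume and its masks live here,
so downstream feature code can assume a validated pair.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: absolute tolerance (mm) when comparing voxel spacings that have
#: round-tripped through 32-bit NIfTI headers
SPACING_ATOL = 1e-4

LABELS = ("aMCI", "NC")
SIDES = ("left", "right")


class FormatError(ValueError):
    """Raised when an input file violates the pipeline's contracts."""


@dataclasses.dataclass
class Volume:
    """A 3D scalar image with physical voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"expected 3D volume, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be positive, got {self.spacing}")
        bad = np.count_nonzero(~np.isfinite(self.data))
        if bad:
            raise FormatError(f"volume contains {bad} non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclasses.dataclass
class Mask:
    """A binary ROI on the same grid as its reference volume."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    side: str | None = None

    def __post_init__(self) -> None:
        self.data = (np.asarray(self.data) != 0).astype(np.uint8)
        if self.data.ndim != 3:
            raise FormatError(f"expected 3D mask, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if not self.data.any():
            raise FormatError("mask has no foreground voxels")
        if self.side is not None and self.side not in SIDES:
            raise FormatError(f"side must be one of {SIDES}, got {self.side!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected 3D volume, got {data.ndim}D in {path.name}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(data, dtype=np.float64), spacing, img.affine


def read_volume(path: str | Path) -> Volume:
    """Load a NIfTI-1 scalar volume, screening for non-finite voxels."""
    data, spacing, affine = _load_nifti(path)
    return Volume(data=data, spacing=spacing, affine=affine)


def write_volume(volume: Volume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path, reference: Volume, side: str | None = None) -> Mask:
    """Load a binary ROI and validate it against its reference volume.

    Any nonzero voxel is treated as foreground.  Shape and voxel
    spacing must match the reference grid (spacing to ``SPACING_ATOL``
    mm); resampling between mismatched grids is out of scope.
    """
    data, spacing, _ = _load_nifti(path)
    if data.shape != reference.shape:
        raise FormatError(
            f"mask grid {data.shape} does not match volume grid {reference.shape}"
        )
    if not np.allclose(spacing, reference.spacing, atol=SPACING_ATOL, rtol=0):
        raise FormatError(
            f"mask spacing {spacing} does not match volume spacing {reference.spacing}"
        )
    return Mask(data=data, spacing=reference.spacing, side=side)


def write_mask(mask: Mask, path: str | Path, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.diag(list(mask.spacing) + [1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


MANIFEST_COLUMNS = [
    "subject_id",
    "label",
    "volume_path",
    "mask_left_path",
    "mask_right_path",
    "age",
    "sex",
    "education",
    "mmse",
]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the per-subject cohort manifest (CSV with a header row).

    Enforces unique subject ids and exactly two label values.
    """
    df = pd.read_csv(path)
    missing = {"subject_id", "label"} - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise FormatError(f"duplicate subject ids: {dupes}")
    labels = set(df["label"].unique())
    if len(labels) != 2:
        raise FormatError(f"expected exactly two label values, got {sorted(labels)}")
    unknown = labels - set(LABELS)
    if unknown:
        raise FormatError(f"unknown label values: {sorted(unknown)}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a subjects×features table, preserving feature names verbatim."""
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Round-trip partner of :func:`write_feature_table`."""
    return pd.read_csv(path)
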