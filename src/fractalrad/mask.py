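"""Binary segmentation-mask I/O and geometry normalisation.

A :class:`VoxelMask` is the in-memory form of a tumour segmentation: a strictly
binary 3D grid plus the physical voxel spacing in millimetres. Masks typically
arrive as NIfTI label maps exported from a segmentation tool; everything
downstream (box counting, lacunarity, shape features) assumes isotropic voxels,
so anisotropic masks must pass through :func:`resample_isotropic` first.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import EmptyMaskError, IntegrityError, MaskDimensionError, MaskFormatError, ParameterError

__all__ = ["VoxelMask", "read_mask", "resample_isotropic", "write_feature_table", "read_table"]

#: fixed trailing column order of feature tables (metadata columns are inserted
#: between subject_id and these)
FEATURE_COLUMNS = ("fd", "lacunarity", "sphericity", "max_diameter_cm", "volume_mm3")


@dataclasses.dataclass
class VoxelMask:
    """A binary 3D voxel grid with physical spacing.

    Parameters
    ----------
    grid
        3D array of {0, 1}; stored as ``uint8``.
    spacing
        Voxel edge lengths in mm along each array axis (all positive).
    subject_id
        Label carried through feature extraction and error messages.
    orientation
        NIfTI axis codes as read from the file, recorded but never used to
        reorder axes (all features are permutation-invariant at the level
        they are defined).
    flags
        Diagnostic markers such as ``"empty"`` or ``"non_isotropic"``.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""
    orientation: tuple[str, str, str] | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise MaskDimensionError(f"mask grid must be 3D, got shape {grid.shape}")
        uniq = np.unique(grid)
        if not np.isin(uniq, (0, 1)).all():
            raise ParameterError(f"mask grid must be binary, found values {uniq[:5]}")
        self.grid = grid.astype(np.uint8, copy=False)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be 3 positive lengths, got {self.spacing}")
        flags = set(self.flags)
        if self.n_foreground == 0:
            flags.add("empty")
        if not self.is_isotropic:
            flags.add("non_isotropic")
        self.flags = frozenset(flags)

    @property
    def n_foreground(self) -> int:
        return int(self.grid.sum())

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0], rtol=1e-6, atol=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        """Foreground volume in mm³ (voxel count × voxel volume)."""
        return self.n_foreground * self.voxel_volume_mm3

    def require_nonempty(self) -> None:
        if self.n_foreground == 0:
            raise EmptyMaskError(f"mask {self.subject_id!r} has no foreground voxels")

    def bounding_box(self) -> tuple[slice, slice, slice]:
        """Tight slices around the foreground (mask must be non-empty)."""
        self.require_nonempty()
        slices = []
        for axis in range(3):
            proj = np.any(self.grid, axis=tuple(a for a in range(3) if a != axis))
            idx = np.flatnonzero(proj)
            slices.append(slice(int(idx[0]), int(idx[-1]) + 1))
        return tuple(slices)


def read_mask(path: str | Path, threshold: float = 0.0, subject_id: str | None = None) -> VoxelMask:
    """Read a NIfTI volume and binarise it at ``value > threshold``.

    Segmentation masks are label maps, so the default threshold 0 keeps every
    labelled voxel; a different threshold accommodates probabilistic masks.
    A 4D volume is accepted only when its trailing axes are singletons.
    An all-background result is not an error here — the mask is flagged
    ``"empty"`` and feature extraction rejects it later.
    """
    path = Path(path)
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise MaskFormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    if data.ndim > 3:
        extra = data.shape[3:]
        if any(n != 1 for n in extra):
            raise MaskDimensionError(
                f"{path}: expected a 3D volume, got shape {data.shape} with {extra} timepoints/components"
            )
        data = data.reshape(data.shape[:3])
    if data.ndim < 3:
        raise MaskDimensionError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    orientation = tuple(nib.aff2axcodes(img.affine))
    grid = (data > threshold).astype(np.uint8)
    return VoxelMask(
        grid=grid,
        spacing=spacing,
        subject_id=subject_id if subject_id is not None else path.name.split(".")[0],
        orientation=orientation,
    )


def write_mask(mask: VoxelMask, path: str | Path) -> None:
    """Write a mask as an uncompressed/compressed NIfTI (extension decides)."""
    affine = np.diag(list(mask.spacing) + [1.0])
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def resample_isotropic(mask: VoxelMask, target_spacing: float | str = "min-axis") -> VoxelMask:
    """Nearest-neighbour resample onto an isotropic grid.

    ``target_spacing`` is the isotropic voxel edge in mm, or ``"min-axis"``
    (default) for the smallest input spacing — the choice that never discards
    in-plane resolution. Nearest-neighbour interpolation keeps the grid
    strictly binary. An already-isotropic mask at the target spacing is
    returned unchanged.
    """
    if isinstance(target_spacing, str):
        if target_spacing != "min-axis":
            raise ParameterError(f"unknown target_spacing {target_spacing!r}")
        target = min(mask.spacing)
    else:
        target = float(target_spacing)
    if target <= 0:
        raise ParameterError(f"target spacing must be positive, got {target}")
    if mask.is_isotropic and np.isclose(mask.spacing[0], target, rtol=1e-6):
        return mask
    zoom = tuple(s / target for s in mask.spacing)
    grid = ndimage.zoom(mask.grid, zoom, order=0, mode="grid-constant", grid_mode=True)
    return VoxelMask(
        grid=(grid > 0).astype(np.uint8),
        spacing=(target, target, target),
        subject_id=mask.subject_id,
        orientation=mask.orientation,
    )


def write_feature_table(
    features: Sequence,
    path: str | Path,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Write per-subject fractal features (plus optional metadata) as CSV.

    Column order is fixed: ``subject_id``, metadata columns (``group`` first
    when present), then ``fd, lacunarity, sphericity, max_diameter_cm,
    volume_mm3``. Numeric fields round-trip through the CSV at full float64
    precision. Raises before creating the file on an empty list or duplicated
    subject ids.
    """
    if len(features) == 0:
        raise ParameterError("no features to write")
    rows = []
    for f in features:
        rows.append(
            {
                "subject_id": f.subject_id,
                "fd": f.fd,
                "lacunarity": f.lacunarity,
                "sphericity": f.sphericity,
                "max_diameter_cm": f.max_diameter_cm,
                "volume_mm3": f.volume_mm3,
            }
        )
    df = pd.DataFrame(rows)
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise IntegrityError(f"duplicate subject_id values: {dupes}")
    meta_cols: list[str] = []
    if metadata is not None:
        meta = metadata.copy()
        if meta.index.name == "subject_id":
            meta = meta.reset_index()
        if "subject_id" not in meta.columns:
            raise IntegrityError("metadata table must carry a subject_id column or index")
        if meta["subject_id"].duplicated().any():
            raise IntegrityError("duplicate subject_id values in metadata")
        meta_cols = [c for c in meta.columns if c != "subject_id"]
        if "group" in meta_cols:  # group leads the covariate block
            meta_cols = ["group"] + [c for c in meta_cols if c != "group"]
        df = df.merge(meta[["subject_id"] + meta_cols], on="subject_id", how="left")
    df = df[["subject_id"] + meta_cols + list(FEATURE_COLUMNS)]
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def read_table(path: str | Path, required: Iterable[str] = ()) -> pd.DataFrame:
    """Read a feature/cohort CSV, checking that required columns are present."""
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IntegrityError(f"{path}: missing required columns {missing}")
    return df
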