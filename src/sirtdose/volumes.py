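"""Voxel grids, volume containers and NIfTI I/O.

All volumes in the pipeline — scintigraphic counts, binary contours,
activity maps (GBq/voxel) and absorbed-dose maps (Gy) — live on an
axis-aligned :class:`VoxelGrid`.  Operations that combine two volumes
require their grids to be aligned (shape, spacing, origin and orientation
matching within ``GRID_TOL_MM``) and raise :class:`GridAlignmentError`
otherwise; nothing is ever silently broadcast between grids.

Conventions
-----------
* Voxel-center coordinates: the physical position of index ``(i, j, k)``
  is ``origin_mm + index * voxel_size_mm`` along each axis.
* Masks are binary uint8 arrays; label resampling is nearest-neighbor
  only, so masks stay binary.
* On disk everything is NIfTI-1 (``.nii`` / ``.nii.gz``) with the grid
  encoded in the affine.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import (
    DimensionalityError,
    GeometryError,
    GridAlignmentError,
    MetadataError,
)

#: Two grids are considered aligned iff every geometric parameter agrees
#: within this tolerance (mm).
GRID_TOL_MM = 1e-6


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of an axis-aligned voxel lattice.

    Parameters
    ----------
    shape
        Number of voxels along each axis, ``(nx, ny, nz)``.
    voxel_size_mm
        Positive voxel edge lengths in mm.
    origin_mm
        Physical position (mm) of the center of voxel ``(0, 0, 0)``.
    orientation
        Axis-direction codes, e.g. ``('R', 'A', 'S')``.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise MetadataError(f"grid shape must be a positive triple, got {self.shape}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise MetadataError(
                f"voxel size must be a positive triple in mm, got {self.voxel_size_mm}"
            )
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))
        object.__setattr__(self, "orientation", tuple(self.orientation))

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm^3)."""
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> physical-mm affine (diagonal, RAS-style)."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        aff[:3, 3] = self.origin_mm
        return aff

    def aligned_with(self, other: "VoxelGrid", tol_mm: float = GRID_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and self.orientation == other.orientation
            and all(
                abs(a - b) <= tol_mm
                for a, b in zip(
                    self.voxel_size_mm + self.origin_mm,
                    other.voxel_size_mm + other.origin_mm,
                )
            )
        )

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (..., 3) to physical mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return idx * np.array(self.voxel_size_mm) + np.array(self.origin_mm)

    def physical_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.array(self.origin_mm)) / np.array(self.voxel_size_mm)


def require_aligned(a: VoxelGrid, b: VoxelGrid, what: str = "volumes") -> None:
    if not a.aligned_with(b):
        raise GridAlignmentError(f"{what} live on different voxel grids: {a} vs {b}")


@dataclass
class Volume:
    """A scalar field on a voxel grid (base container)."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D scalar volume, got ndim={self.values.ndim}"
            )
        if tuple(self.values.shape) != self.grid.shape:
            raise GridAlignmentError(
                f"array shape {self.values.shape} does not match grid shape {self.grid.shape}"
            )


@dataclass
class CountVolume(Volume):
    """Scintigraphic counts per voxel (SPECT-like or PET-like)."""

    modality: str = "SPECT-like"

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(float)
        if not np.all(np.isfinite(self.values)):
            raise MetadataError("count volume contains non-finite values")
        if np.any(self.values < 0):
            raise MetadataError("count volume contains negative values")


@dataclass
class ContourMask(Volume):
    """Binary region on a grid (liver, tumor, normal liver, threshold target)."""

    label: str = "mask"

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.asarray(self.values)
        uniq = np.unique(vals)
        if not np.all(np.isin(uniq, (0, 1))):
            raise MetadataError(f"mask must be binary, found values {uniq[:5]}")
        self.values = vals.astype(np.uint8)

    @property
    def volume_ml(self) -> float:
        return float(self.values.sum()) * self.grid.voxel_volume_ml

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def __and__(self, other: "ContourMask") -> "ContourMask":
        require_aligned(self.grid, other.grid, "masks")
        return ContourMask(self.grid, self.values & other.values,
                           label=f"{self.label}&{other.label}")


@dataclass
class ActivityMap(Volume):
    """Activity per voxel in GBq."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(float)
        if np.any(self.values < 0):
            raise MetadataError("activity map contains negative values")

    @property
    def total_gbq(self) -> float:
        return float(self.values.sum())


@dataclass
class DoseMap(Volume):
    """Absorbed dose per voxel in Gy."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(float)
        if np.any(self.values < 0):
            raise MetadataError("dose map contains negative values")


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _grid_from_nifti(img: nib.Nifti1Image) -> VoxelGrid:
    data_shape = img.shape
    if len(data_shape) != 3:
        raise DimensionalityError(
            f"expected a 3D volume, file has shape {data_shape}"
        )
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise MetadataError(f"missing or invalid voxel spacing {zooms}")
    aff = img.affine
    orientation = nib.aff2axcodes(aff)
    origin = tuple(float(v) for v in aff[:3, 3])
    return VoxelGrid(
        shape=tuple(int(s) for s in data_shape),
        voxel_size_mm=tuple(float(z) for z in zooms),
        origin_mm=origin,
        orientation=orientation,
    )


def read_volume(path: str | Path, modality: str = "SPECT-like") -> CountVolume:
    """Read a 3D scalar NIfTI volume as a :class:`CountVolume`."""
    img = nib.load(str(path))
    grid = _grid_from_nifti(img)
    data = np.asarray(img.dataobj, dtype=float)
    return CountVolume(grid, data, modality=modality)


def read_mask(path: str | Path, label: str = "mask") -> ContourMask:
    """Read a binary NIfTI mask (any nonzero voxel becomes 1)."""
    img = nib.load(str(path))
    grid = _grid_from_nifti(img)
    data = (np.asarray(img.dataobj) != 0).astype(np.uint8)
    return ContourMask(grid, data, label=label)


def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write any volume container to NIfTI-1; round-trips bit-exactly."""
    path = Path(path)
    data = volume.values
    if isinstance(volume, ContourMask):
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float64)
    img = nib.Nifti1Image(data, volume.grid.affine())
    img.header.set_zooms(volume.grid.voxel_size_mm)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Mask resampling
# ---------------------------------------------------------------------------

def resample_mask(mask: ContourMask, target_grid: VoxelGrid) -> ContourMask:
    """Resample a binary mask onto ``target_grid`` by nearest neighbor.

    Each target voxel center is mapped to physical space and assigned the
    value of the nearest source voxel; positions outside the source extent
    get 0.  Resampling onto the mask's own grid is the identity.

    Raises
    ------
    GeometryError
        If the physical extents of the two grids are disjoint.
    """
    if mask.grid.aligned_with(target_grid):
        return ContourMask(target_grid, mask.values.copy(), label=mask.label)
    if mask.grid.orientation != target_grid.orientation:
        raise GeometryError(
            "resampling between differently oriented grids is not supported"
        )
    tg = target_grid
    axes_idx = [np.arange(n, dtype=float) for n in tg.shape]
    # physical coordinate of every target voxel center, one axis at a time
    # (grids are axis-aligned so the mapping separates per axis)
    src_idx = []
    inside = []
    for ax in range(3):
        phys = axes_idx[ax] * tg.voxel_size_mm[ax] + tg.origin_mm[ax]
        fi = (phys - mask.grid.origin_mm[ax]) / mask.grid.voxel_size_mm[ax]
        ri = np.rint(fi).astype(int)
        ok = (ri >= 0) & (ri < mask.grid.shape[ax])
        src_idx.append(np.clip(ri, 0, mask.grid.shape[ax] - 1))
        inside.append(ok)
    if not all(ok.any() for ok in inside):
        raise GeometryError("target grid does not overlap the mask's physical extent")
    out = mask.values[np.ix_(src_idx[0], src_idx[1], src_idx[2])].copy()
    out[~inside[0], :, :] = 0
    out[:, ~inside[1], :] = 0
    out[:, :, ~inside[2]] = 0
    return ContourMask(tg, out, label=mask.label)
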