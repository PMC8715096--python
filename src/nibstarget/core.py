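"""Shared spatial containers: voxel grids, statistical maps, masks, BOLD series.

Every volumetric object in the pipeline lives on a :class:`VolumeGrid` — a
shape plus a voxel-to-MNI-mm affine — so that maps produced at different
stages can be checked for spatial compatibility before any voxelwise
arithmetic.  NIfTI-1 reading/writing goes through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "StatMap",
    "BinaryMask",
    "BoldSeries",
    "MotionTrace",
    "connectivity_structure",
    "load_stat_map",
    "load_binary_mask",
    "load_bold",
]

# Working resolution of the pipeline (mm); all defaults assume isotropic 3 mm.
DEFAULT_VOXEL_MM = 3.0
DEFAULT_SHAPE = (20, 24, 20)


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel lattice with a voxel-index -> MNI-mm affine.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along x, y, z.
    affine : (4, 4) ndarray
        Homogeneous matrix mapping voxel indices (i, j, k, 1) to MNI mm.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine upper-left 3x3 must be invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def default(cls) -> "VolumeGrid":
        """Desk-scale 20 x 24 x 20 grid at 3 mm centered on the MNI origin."""
        return cls.isotropic(DEFAULT_SHAPE, DEFAULT_VOXEL_MM)

    @classmethod
    def isotropic(cls, shape: Sequence[int], voxel_mm: float) -> "VolumeGrid":
        shape = tuple(int(s) for s in shape)
        affine = np.eye(4)
        affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_mm
        # grid center sits on the MNI origin
        affine[:3, 3] = -voxel_mm * (np.array(shape) - 1) / 2.0
        return cls(shape, affine)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge length in mm, derived from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        mm = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return mm[0] if mm.shape[0] == 1 else mm

    def mm_to_voxel(self, mm: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of MNI-mm points (inverse affine)."""
        mm = np.atleast_2d(np.asarray(mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        ijk = mm @ inv[:3, :3].T + inv[:3, 3]
        return ijk[0] if ijk.shape[0] == 1 else ijk

    def mm_to_index(self, mm: np.ndarray) -> tuple[int, int, int]:
        """Nearest voxel index of an MNI-mm point; raises if outside the grid."""
        ijk = np.round(self.mm_to_voxel(mm)).astype(int)
        if ijk.ndim != 1:
            raise ValueError("mm_to_index expects a single point")
        if np.any(ijk < 0) or np.any(ijk >= np.array(self.shape)):
            raise ValueError(f"point {np.asarray(mm)} maps to voxel {tuple(ijk)} outside grid {self.shape}")
        return tuple(int(v) for v in ijk)

    def contains_mm(self, mm: np.ndarray) -> bool:
        ijk = np.round(self.mm_to_voxel(mm)).astype(int)
        return bool(np.all(ijk >= 0) and np.all(ijk < np.array(self.shape)))

    def voxel_centers_mm(self) -> np.ndarray:
        """(n_voxels, 3) MNI-mm coordinates of every voxel center, C order."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.voxel_to_mm(idx)

    def matches(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    def require_match(self, other: "VolumeGrid") -> None:
        if not self.matches(other):
            raise ValueError("volume grids do not match (shape/affine mismatch)")


def _check_grid_data(grid: VolumeGrid, data: np.ndarray, ndim: int) -> None:
    if data.shape[:3] != grid.shape:
        raise ValueError(f"data shape {data.shape} inconsistent with grid {grid.shape}")
    if data.ndim != ndim:
        raise ValueError(f"expected {ndim}-D data, got {data.ndim}-D")


@dataclass
class StatMap:
    """Scalar values (z, t, r, counts ...) on a grid."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        _check_grid_data(self.grid, self.data, 3)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float64), self.grid.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))


@dataclass
class BinaryMask:
    """Boolean membership on a grid."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        _check_grid_data(self.grid, self.data, 3)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return not self.data.any()

    def intersect(self, other: "BinaryMask") -> "BinaryMask":
        self.grid.require_match(other.grid)
        return BinaryMask(self.grid, self.data & other.data)

    def union(self, other: "BinaryMask") -> "BinaryMask":
        self.grid.require_match(other.grid)
        return BinaryMask(self.grid, self.data | other.data)

    def disjoint(self, other: "BinaryMask") -> bool:
        self.grid.require_match(other.grid)
        return not np.any(self.data & other.data)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.uint8), self.grid.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))


@dataclass
class BoldSeries:
    """One subject's 4-D BOLD series (x, y, z, t) with repetition time in s."""

    grid: VolumeGrid
    data: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        _check_grid_data(self.grid, self.data, 4)
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD series needs at least 2 volumes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[3])

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.grid.affine)
        img.header.set_zooms((*self.grid.voxel_size_mm, self.tr_s))
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))


@dataclass
class MotionTrace:
    """Per-volume rigid-motion parameters: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must be (n_volumes, 6)")

    @property
    def n_volumes(self) -> int:
        return int(self.params.shape[0])

    def save(self, path: str | Path) -> None:
        np.savetxt(str(path), self.params, fmt="%.10g")

    @classmethod
    def load(cls, path: str | Path) -> "MotionTrace":
        return cls(np.loadtxt(str(path), ndmin=2))


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3-D binary structuring element for 6-, 18- or 26-connectivity."""
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, order[connectivity])


def _grid_from_img(img: nib.Nifti1Image) -> VolumeGrid:
    return VolumeGrid(tuple(img.shape[:3]), np.asarray(img.affine))


def load_stat_map(path: str | Path) -> StatMap:
    img = nib.load(str(path))
    return StatMap(_grid_from_img(img), np.asarray(img.dataobj, dtype=float))


def load_binary_mask(path: str | Path) -> BinaryMask:
    img = nib.load(str(path))
    return BinaryMask(_grid_from_img(img), np.asarray(img.dataobj) > 0)


def load_bold(path: str | Path, tr_s: float | None = None) -> BoldSeries:
    img = nib.load(str(path))
    if tr_s is None:
        zooms = img.header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return BoldSeries(_grid_from_img(img), np.asarray(img.dataobj, dtype=float), tr_s)
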