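"""Core 3D volume and mask types with NIfTI I/O and brain-mask extraction.

A :class:`Volume` is a scalar field in Hounsfield units (HU) on a regular
grid with world geometry (per-axis spacing in mm, origin, and an orthonormal
direction matrix).  Values are stored as ``float64`` internally regardless of
the on-disk dtype so that downstream atlas statistics are exact.  World
coordinates follow the NIfTI affine convention: ``world = origin +
direction @ diag(spacing) @ index``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "compute_brain_mask",
    "GEOM_TOL_MM",
]

#: Tolerance (mm) for all geometry comparisons.
GEOM_TOL_MM = 1e-5


class VolumeError(ValueError):
    """Raised for invalid volume inputs (bad files, bad geometry, bad values)."""


@dataclass
class Volume:
    """A 3D scalar field in HU with grid geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel intensities in Hounsfield units; must be finite.
    spacing : array-like of 3 floats
        Per-axis voxel size in mm, strictly positive.
    origin : array-like of 3 floats
        World coordinate of voxel (0, 0, 0) in mm.
    direction : ndarray, shape (3, 3)
        Orthonormal direction matrix mapping index axes to world axes.
    """

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.direction = np.asarray(self.direction, dtype=np.float64).reshape(3, 3)
        if self.values.ndim != 3:
            raise VolumeError(f"volume must be 3D, got {self.values.ndim}D")
        if any(s < 2 for s in self.values.shape):
            raise VolumeError(f"grid dimensions must be >= 2, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise VolumeError("volume contains non-finite voxels")
        if np.any(self.spacing <= 0):
            raise VolumeError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise VolumeError("direction matrix must be orthonormal")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (NIfTI convention)."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction @ np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def same_geometry(self, other: "Volume | BinaryMask", tol: float = GEOM_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=1e-6)
        )

    def with_values(self, values: np.ndarray) -> "Volume":
        """A new Volume on the same grid with different voxel values."""
        return Volume(values, self.spacing.copy(), self.origin.copy(), self.direction.copy())

    def copy(self) -> "Volume":
        return self.with_values(self.values.copy())


@dataclass
class BinaryMask:
    """A boolean grid sharing geometry with an associated :class:`Volume`."""

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.direction = np.asarray(self.direction, dtype=np.float64).reshape(3, 3)
        if self.values.ndim != 3:
            raise VolumeError(f"mask must be 3D, got {self.values.ndim}D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = self.direction @ np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def same_geometry(self, other: "Volume | BinaryMask", tol: float = GEOM_TOL_MM) -> bool:
        return Volume.same_geometry(self, other, tol)  # type: ignore[arg-type]

    @classmethod
    def like(cls, ref: "Volume | BinaryMask", values: np.ndarray) -> "BinaryMask":
        return cls(values, ref.spacing.copy(), ref.origin.copy(), ref.direction.copy())


def _geometry_from_affine(affine: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    linear = affine[:3, :3]
    spacing = np.linalg.norm(linear, axis=0)
    direction = linear / spacing
    return spacing, affine[:3, 3].copy(), direction


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a scalar 3D NIfTI-1/2 volume.

    Raises :class:`VolumeError` if the file is unreadable, not 3D, or
    contains non-finite voxels.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise VolumeError(f"cannot read NIfTI volume {path!r}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise VolumeError(f"{path!r}: expected a 3D scalar volume, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise VolumeError(f"{path!r}: volume contains non-finite voxels")
    spacing, origin, direction = _geometry_from_affine(np.asarray(img.affine))
    return Volume(data, spacing, origin, direction)


def write_volume(v: Volume, path: str | os.PathLike, dtype=np.float64) -> None:
    """Write a Volume to NIfTI so that re-reading it reproduces values exactly
    (for lossless dtypes) and geometry within :data:`GEOM_TOL_MM`."""
    img = nib.Nifti1Image(v.values.astype(dtype), v.affine)
    img.header.set_zooms(tuple(v.spacing))
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a NIfTI mask; any nonzero voxel is True."""
    v = read_volume(path)
    return BinaryMask(v.values != 0, v.spacing, v.origin, v.direction)


def write_mask(m: BinaryMask, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(m.values.astype(np.uint8), m.affine)
    img.header.set_zooms(tuple(m.spacing))
    nib.save(img, str(path))


# 26-connectivity structuring element used throughout the package.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def compute_brain_mask(
    v: Volume, hu_window: tuple[float, float] = (0.0, 80.0)
) -> BinaryMask:
    """Extract a brain mask from a head volume.

    Voxels within the soft-tissue HU window (default 0–80 HU) are kept,
    restricted to the largest 26-connected component, and interior holes
    (e.g. low-HU ventricles) are filled.  Raises :class:`VolumeError`
    if no voxel falls inside the window.
    """
    lo, hi = hu_window
    window = (v.values >= lo) & (v.values <= hi)
    if not window.any():
        raise VolumeError(
            f"no brain-like tissue found: no voxel in HU window [{lo}, {hi}]"
        )
    labels, n = ndimage.label(window, structure=STRUCT_26)
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        largest = sizes.argmax()
        window = labels == largest
    filled = ndimage.binary_fill_holes(window)
    return BinaryMask.like(v, filled)
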