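"""CT-like intensity volumes on regular millimetre grids.

Arrays are indexed ``[ix, iy, iz]`` with a fixed (x, y, z) axis order;
``origin`` is the world coordinate of the *center* of voxel (0, 0, 0) and
``spacing`` the isotropic or anisotropic voxel edge lengths in mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Grid", "CTVolume", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Raised when two volumes that must share a grid do not."""


@dataclass(frozen=True)
class Grid:
    """Geometry of a regular voxel grid (no intensities)."""

    shape: tuple
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", np.asarray(self.spacing, dtype=float).reshape(3))
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        if len(self.shape) != 3 or any(s < 2 for s in self.shape):
            raise ValueError(f"grid shape must be 3-D with ≥2 voxels per axis: {self.shape}")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def axis_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world points (no rounding)."""
        return (np.atleast_2d(np.asarray(points, float)) - self.origin) / self.spacing

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(indices, float)) * self.spacing + self.origin

    def matches(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=tol)
                and np.allclose(self.origin, other.origin, atol=tol))

    def require_match(self, other: "Grid") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}")


@dataclass
class CTVolume:
    """Scalar intensity volume (HU-like, arbitrary units) on a `Grid`."""

    intensities: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3-D array")
        if any(s < 2 for s in self.intensities.shape):
            raise ValueError("volume must have at least 2 voxels per axis")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("volume intensities must be finite")

    @property
    def grid(self) -> Grid:
        return Grid(self.intensities.shape, self.spacing, self.origin)

    def copy(self) -> "CTVolume":
        return CTVolume(self.intensities.copy(), self.spacing.copy(), self.origin.copy())

    # -- NIfTI round trip ---------------------------------------------------

    def to_nifti(self, path) -> None:
        affine = np.diag([*self.spacing, 1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(np.asarray(self.intensities, np.float32), affine),
                 str(path))

    @classmethod
    def from_nifti(cls, path) -> "CTVolume":
        img = nib.load(str(Path(path)))
        affine = img.affine
        data = np.asarray(img.get_fdata(), dtype=np.float32)
        spacing = np.linalg.norm(affine[:3, :3], axis=0)
        return cls(data, spacing, affine[:3, 3])
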