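"""Digitally-reconstructed-radiograph volume construction.

The tracking stage does not consume surface meshes directly: each rigid
object is represented by an intensity volume (its "DRR model") whose
perspective projections are matched against the fluoroscopy images.  The
construction follows a fixed recipe:

1. surfaces are converted to slice-by-slice binary stacks (1 where the
   object is, 0 elsewhere, by a voxel-center in/out test);
2. bone intensity is obtained by element-wise multiplication of the CT
   volume with the bone's binary stack (arithmetic isolation);
3. implant binary stacks are hollowed slice-wise, retaining only the 2-D
   boundary of each slice, which mimics the dense cortical shell and gives
   the edge-detection tracker clean implant contours without saturation;
4. intensities are conditioned: bone is dimmed to 60 % and the (uniform)
   implant edge intensity is magnified ×100 so both remain visible in one
   rendering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import CTVolume, Grid, GridMismatchError

__all__ = [
    "DRRVolume",
    "NonWatertightMeshError",
    "mesh_to_binary_stack",
    "rasterize_occupancy",
    "isolate_bone",
    "hollow_implant",
    "condition_intensities",
    "BONE_ATTENUATION_FACTOR",
    "IMPLANT_INTENSITY_GAIN",
    "IMPLANT_REFERENCE_INTENSITY",
]

#: Bone intensities are reduced to this fraction ("decreased by 0.6 (60%)",
#: read as retain 60 %; the subtractive reading — retain 40 % — is available
#: via ``condition_intensities(..., bone_mode="subtract")``).
BONE_ATTENUATION_FACTOR = 0.6
#: Implant intensities are magnified by this factor.
IMPLANT_INTENSITY_GAIN = 100.0
#: Uniform synthetic intensity assigned to implant voxels before scaling
#: (CAD geometry carries no HU data).  30 × the ×100 gain lands the hollow
#: edge at the top of the CT intensity range, balancing the 0.6-dimmed bone
#: so both stay visible in one rendering.
IMPLANT_REFERENCE_INTENSITY = 30.0


class NonWatertightMeshError(ValueError):
    """Raised when rasterization is attempted on a non-watertight mesh."""


@dataclass
class DRRVolume:
    """Intensity volume used for projection, tagged with its provenance."""

    intensities: np.ndarray
    grid: Grid
    provenance: str = "bone"  # bone | implant | hybrid
    scale_applied: float = 1.0

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.shape != self.grid.shape:
            raise GridMismatchError("DRR intensities do not match grid shape")

    @property
    def support(self) -> np.ndarray:
        return self.intensities != 0

    def copy(self) -> "DRRVolume":
        return DRRVolume(self.intensities.copy(), self.grid,
                         self.provenance, self.scale_applied)


# ---------------------------------------------------------------------------
# Rasterization: mesh -> slice-by-slice binary stack
# ---------------------------------------------------------------------------

def _cross2(ax, ay, bx, by):
    return ax * by - ay * bx


def mesh_to_binary_stack(mesh, grid: Grid) -> np.ndarray:
    """Voxelize a watertight mesh: voxel = 1 iff its center lies inside.

    Implemented with a vertical-ray parity count per (x, y) voxel column:
    a voxel center is interior when an odd number of triangle crossings lie
    above it.  Rays are jittered by a sub-nanometre offset so they never
    pass exactly through projected triangle edges.
    """
    if not mesh.is_watertight:
        raise NonWatertightMeshError(
            "mesh is not watertight (open boundary or non-manifold edges); "
            "voxel in/out test undefined")

    xc = grid.axis_centers(0) + 1.03e-7 * grid.spacing[0]
    yc = grid.axis_centers(1) + 2.17e-7 * grid.spacing[1]
    zc = grid.axis_centers(2)
    out = np.zeros(grid.shape, dtype=bool)

    lo, hi = mesh.bounds
    grid_lo = np.array([xc[0], yc[0], zc[0]]) - 0.5 * grid.spacing
    grid_hi = np.array([xc[-1], yc[-1], zc[-1]]) + 0.5 * grid.spacing
    if np.any(hi < grid_lo) or np.any(lo > grid_hi):
        warnings.warn("mesh lies entirely outside the grid; empty stack",
                      stacklevel=2)
        return out

    tris = mesh.triangles  # (n, 3, 3)
    col_hits: list[np.ndarray] = []  # flat column index per crossing
    z_hits: list[np.ndarray] = []
    ny = len(yc)

    for A, B, C in tris:
        v0 = B - A
        v1 = C - A
        denom = _cross2(v0[0], v0[1], v1[0], v1[1])
        if abs(denom) < 1e-14:
            continue  # triangle vertical in z: ray-parallel, no crossing
        xmin, xmax = min(A[0], B[0], C[0]), max(A[0], B[0], C[0])
        ymin, ymax = min(A[1], B[1], C[1]), max(A[1], B[1], C[1])
        i0 = int(np.searchsorted(xc, xmin, side="left"))
        i1 = int(np.searchsorted(xc, xmax, side="right"))
        j0 = int(np.searchsorted(yc, ymin, side="left"))
        j1 = int(np.searchsorted(yc, ymax, side="right"))
        if i0 >= i1 or j0 >= j1:
            continue
        gx, gy = np.meshgrid(xc[i0:i1], yc[j0:j1], indexing="ij")
        wx = gx - A[0]
        wy = gy - A[1]
        u = _cross2(wx, wy, v1[0], v1[1]) / denom
        v = _cross2(v0[0], v0[1], wx, wy) / denom
        inside = (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0)
        if not inside.any():
            continue
        zc_hit = A[2] + u[inside] * v0[2] + v[inside] * v1[2]
        ii, jj = np.nonzero(inside)
        col_hits.append((ii + i0) * ny + (jj + j0))
        z_hits.append(zc_hit)

    if not col_hits:
        warnings.warn("mesh produced no voxel-column crossings; empty stack",
                      stacklevel=2)
        return out

    cols = np.concatenate(col_hits)
    zs = np.concatenate(z_hits)
    order = np.argsort(cols, kind="stable")
    cols = cols[order]
    zs = zs[order]
    starts = np.searchsorted(cols, np.arange(len(xc) * ny))
    ends = np.append(starts[1:], len(cols))
    for flat in np.unique(cols):
        seg = np.sort(zs[starts[flat]:ends[flat]])
        # crossings strictly above the voxel center, odd => inside
        above = len(seg) - np.searchsorted(seg, zc, side="right")
        ix, iy = divmod(flat, ny)
        out[ix, iy, :] = (above % 2) == 1
    return out


def rasterize_occupancy(mesh, grid: Grid, supersample: int = 3) -> np.ndarray:
    """Antialiased rasterization: fractional voxel occupancy in [0, 1].

    Each voxel is subdivided ``supersample``³ ways and the binary
    in/out test is averaged, so a projected silhouette's position is
    accurate to a fraction of a voxel and independent of the grid phase —
    the right model for an exact CAD solid.
    """
    ss = int(supersample)
    if ss < 1:
        raise ValueError("supersample must be >= 1")
    if ss == 1:
        return mesh_to_binary_stack(mesh, grid).astype(np.float32)
    fine_spacing = grid.spacing / ss
    fine_origin = grid.origin - grid.spacing / 2.0 + fine_spacing / 2.0
    fine = Grid(tuple(np.array(grid.shape) * ss), fine_spacing, fine_origin)
    mask = mesh_to_binary_stack(mesh, fine).astype(np.float32)
    nx, ny, nz = grid.shape
    return mask.reshape(nx, ss, ny, ss, nz, ss).mean(axis=(1, 3, 5))


def isolate_bone(ct: CTVolume, bone_mask: np.ndarray) -> DRRVolume:
    """Arithmetic bone isolation: CT intensities × binary mask."""
    bone_mask = np.asarray(bone_mask)
    if bone_mask.shape != ct.intensities.shape:
        raise GridMismatchError("bone mask shape does not match CT volume")
    iso = ct.intensities * (bone_mask != 0)
    return DRRVolume(iso, ct.grid, provenance="bone")


def hollow_implant(binary: np.ndarray, slice_axis: int = 2) -> np.ndarray:
    """Retain only the per-slice 2-D boundary of a binary implant stack.

    ``out = in AND NOT erode2D(in)`` slice by slice (4-connected erosion,
    background outside the slice).  Regions too thin to survive erosion pass
    through unchanged, since their erosion is empty.
    """
    binary = np.asarray(binary)
    vals = np.unique(binary)
    if not np.all(np.isin(vals, [0, 1])):
        raise ValueError("hollow_implant requires a binary (0/1) volume")
    b = binary.astype(bool)
    moved = np.moveaxis(b, slice_axis, 0)
    structure = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
    out = np.empty_like(moved)
    for k in range(moved.shape[0]):
        sl = moved[k]
        out[k] = sl & ~ndimage.binary_erosion(sl, structure=structure,
                                              border_value=0)
    return np.moveaxis(out, 0, slice_axis).astype(binary.dtype)


def condition_intensities(drr: DRRVolume, role: str,
                          bone_mode: str = "multiply",
                          implant_reference: float = IMPLANT_REFERENCE_INTENSITY
                          ) -> DRRVolume:
    """Apply the bone/implant intensity conditioning.

    ``role="bone"``: multiply by 0.6 (or retain 40 % with
    ``bone_mode="subtract"``).  ``role="implant"``: set support voxels to a
    uniform reference intensity and magnify ×100.
    """
    if role == "bone":
        if bone_mode == "multiply":
            factor = BONE_ATTENUATION_FACTOR
        elif bone_mode == "subtract":
            factor = 1.0 - BONE_ATTENUATION_FACTOR
        else:
            raise ValueError(f"unknown bone_mode: {bone_mode!r}")
        out = drr.intensities * factor
        return DRRVolume(out, drr.grid, "bone", factor)
    if role == "implant":
        gain = IMPLANT_INTENSITY_GAIN
        out = np.where(drr.intensities != 0, implant_reference * gain, 0.0)
        return DRRVolume(out, drr.grid, "implant", gain)
    raise ValueError(f"unknown DRR role: {role!r} (expected 'bone' or 'implant')")
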