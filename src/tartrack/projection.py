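"""Point-source perspective projection geometry and DRR ray casting.

One fluoroscope is modelled as an ideal pinhole system: an X-ray point
source and a planar detector with an orthonormal pixel grid.  A rendered
image is the line integral of a posed intensity volume along each
source-to-pixel ray (image-intensifier distortion and X-ray spectra are
out of scope).  The same renderer serves both the synthetic phantom image
generator and the model-based tracker, which is what makes a projected DRR
directly comparable with a phantom fluoroscopy frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import RigidTransform
from .volume import Grid

__all__ = ["CameraModel", "DegenerateCameraError", "project_volume",
           "default_biplane_rig"]


class DegenerateCameraError(ValueError):
    """Raised for cameras whose geometry cannot form a projection."""


@dataclass(frozen=True)
class CameraModel:
    """Pinhole fluoroscope: point source + planar detector pixel grid.

    ``detector_origin`` is the world position of the *center* of pixel
    (row 0, col 0); ``u_axis``/``v_axis`` are unit directions of increasing
    column/row; ``resolution`` is (n_cols, n_rows).
    """

    source: np.ndarray
    detector_origin: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    pixel_pitch_mm: float
    resolution: tuple = (608, 600)

    def __post_init__(self):
        for name in ("source", "detector_origin", "u_axis", "v_axis"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float).reshape(3))
        object.__setattr__(self, "resolution",
                           (int(self.resolution[0]), int(self.resolution[1])))
        u, v = self.u_axis, self.v_axis
        if (abs(np.linalg.norm(u) - 1) > 1e-9 or abs(np.linalg.norm(v) - 1) > 1e-9
                or abs(np.dot(u, v)) > 1e-9):
            raise DegenerateCameraError("detector axes must be orthonormal")
        if self.pixel_pitch_mm <= 0:
            raise DegenerateCameraError("pixel pitch must be positive")
        if abs(np.dot(self.source - self.detector_origin, self.normal)) < 1e-6:
            raise DegenerateCameraError("source lies on the detector plane")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.u_axis, self.v_axis)

    @property
    def n_cols(self) -> int:
        return self.resolution[0]

    @property
    def n_rows(self) -> int:
        return self.resolution[1]

    @property
    def principal_distance_mm(self) -> float:
        """Perpendicular source-to-detector distance."""
        return float(abs(np.dot(self.source - self.detector_origin, self.normal)))

    def pixel_centers(self) -> np.ndarray:
        """World positions of all pixel centers, shape (n_rows, n_cols, 3)."""
        cols = np.arange(self.n_cols) * self.pixel_pitch_mm
        rows = np.arange(self.n_rows) * self.pixel_pitch_mm
        return (self.detector_origin
                + rows[:, None, None] * self.v_axis
                + cols[None, :, None] * self.u_axis)

    def project_points(self, points: np.ndarray) -> np.ndarray:
        """Pinhole projection of world points to (col, row) pixel coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = self.normal
        d = self.detector_origin
        w = pts - self.source
        denom = w @ n
        if np.any(np.abs(denom) < 1e-12):
            raise DegenerateCameraError("ray parallel to detector plane")
        t = ((d - self.source) @ n) / denom
        hit = self.source + t[:, None] * w
        rel = hit - d
        col = rel @ self.u_axis / self.pixel_pitch_mm
        row = rel @ self.v_axis / self.pixel_pitch_mm
        return np.stack([col, row], axis=1)

    # -- JSON calibration ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "source_mm": self.source.tolist(),
            "detector_origin_mm": self.detector_origin.tolist(),
            "detector_col_axis": self.u_axis.tolist(),
            "detector_row_axis": self.v_axis.tolist(),
            "pixel_pitch_mm": self.pixel_pitch_mm,
            "resolution": list(self.resolution),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(d["source_mm"], d["detector_origin_mm"],
                   d["detector_col_axis"], d["detector_row_axis"],
                   d["pixel_pitch_mm"], tuple(d["resolution"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "CameraModel":
        return cls.from_dict(json.loads(text))


def project_volume(intensities: np.ndarray, grid: Grid,
                   pose: RigidTransform | None, camera: CameraModel,
                   step_mm: float | None = None,
                   window=None) -> np.ndarray:
    """Perspective line integral of a posed volume onto the detector.

    ``pose`` maps model coordinates into the camera's world space (``None``
    for identity).  Sampling is trilinear at ``step_mm`` intervals
    (default: the smallest voxel edge) between each ray's entry and exit of
    the volume's bounding box; the result is linear in the volume intensity.
    ``window`` = (row_slice, col_slice) restricts rendering to a detector
    sub-rectangle and returns just that crop.
    """
    vol = np.ascontiguousarray(intensities, dtype=np.float32)
    if step_mm is None:
        step_mm = float(np.min(grid.spacing))
    centers = camera.pixel_centers()
    if window is not None:
        centers = centers[window[0], window[1]]
    image = np.zeros(centers.shape[:2], dtype=np.float32)

    # Work in model space: pull the source and pixel grid back through pose.
    if pose is None:
        inv_R, inv_t = np.eye(3), np.zeros(3)
    else:
        inv_R, inv_t = pose.rotation.T, -pose.rotation.T @ pose.translation
    src = inv_R @ camera.source + inv_t
    pix = centers.reshape(-1, 3) @ inv_R.T + inv_t

    dirs = pix - src
    lo = grid.origin - 0.5 * grid.spacing
    hi = grid.origin + (np.array(grid.shape) - 0.5) * grid.spacing

    # Slab clipping of every ray against the volume AABB.
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - src) / dirs
        t2 = (hi - src) / dirs
    tmin = np.minimum(t1, t2)
    tmax = np.maximum(t1, t2)
    # Rays parallel to an axis: valid only if inside that slab.
    par = np.abs(dirs) < 1e-12
    inside = (src >= lo) & (src <= hi)
    tmin[par] = np.where(inside[np.nonzero(par)[1]], -np.inf, np.inf)
    tmax[par] = np.where(inside[np.nonzero(par)[1]], np.inf, -np.inf)
    t_near = np.maximum(tmin.max(axis=1), 0.0)
    t_far = tmax.min(axis=1)
    hit = t_far > t_near
    if not np.any(hit):
        return image

    ray_len_mm = np.linalg.norm(dirs[hit], axis=1) * (t_far[hit] - t_near[hit])
    n_steps = max(2, int(np.ceil(ray_len_mm.max() / step_mm)))
    frac = (np.arange(n_steps) + 0.5) / n_steps
    t_samp = t_near[hit, None] + (t_far[hit] - t_near[hit])[:, None] * frac
    pts = src + dirs[hit, None, :] * t_samp[:, :, None]
    vox = ((pts - grid.origin) / grid.spacing).astype(np.float32)
    samples = ndimage.map_coordinates(
        vol, vox.reshape(-1, 3).T, order=1, mode="constant", cval=0.0,
        prefilter=False).reshape(pts.shape[:2])
    dt_mm = ray_len_mm / n_steps
    vals = samples.sum(axis=1) * dt_mm
    image.reshape(-1)[np.nonzero(hit)[0]] = vals
    return image


def default_biplane_rig(center, resolution: int = 160, fov_mm: float = 140.0,
                        source_distance_mm: float = 700.0,
                        detector_distance_mm: float = 300.0,
                        ) -> tuple[CameraModel, CameraModel]:
    """Two pinhole fluoroscopes ~90° apart looking at ``center``.

    Camera 1 views along +y (source anterior... source at −y side), camera 2
    along +x.  ``fov_mm`` is the field of view at the ``center`` plane; the
    pixel pitch accounts for the perspective magnification
    ``(sd + dd) / sd``.
    """
    center = np.asarray(center, dtype=float)
    mag = (source_distance_mm + detector_distance_mm) / source_distance_mm
    pitch = fov_mm * mag / resolution
    cams = []
    for view_dir, u, v in (
        (np.array([0.0, 1.0, 0.0]), np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, -1.0])),
        (np.array([1.0, 0.0, 0.0]), np.array([0.0, -1.0, 0.0]), np.array([0.0, 0.0, -1.0])),
    ):
        source = center - source_distance_mm * view_dir
        det_center = center + detector_distance_mm * view_dir
        origin = (det_center - 0.5 * (resolution - 1) * pitch * u
                  - 0.5 * (resolution - 1) * pitch * v)
        cams.append(CameraModel(source, origin, u, v, pitch,
                                (resolution, resolution)))
    return cams[0], cams[1]
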