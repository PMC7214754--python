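"""Articular-surface distance maps for tracking verification.

The polymer insert is invisible on fluoroscopy, but because it is rigidly
fixed to the tibial tray its articular face can be carried along with the
tracked tibial hybrid model and compared against the tracked talar
component.  A per-vertex signed distance from the selected polymer face to
the talar dome surface (negative = penetration into the dome, positive =
gap) then grades the plausibility of the 3-D tracking solution: per-frame
mean distances must stay strictly inside the (−0.5 mm, +1.5 mm) band.

Closest-point distances and inside/outside tests are computed with
vectorized point-triangle primitives (no spatial index required at the
patch/implant mesh sizes involved).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .geometry import Pose, RigidTransform, compose

__all__ = ["DistanceMap", "PENETRATION_LIMIT_MM", "GAP_LIMIT_MM",
           "place_polymer", "signed_distance", "trial_summary",
           "save_distance_ply", "maps_to_csv",
           "closest_point_distance", "points_in_mesh"]

#: Acceptance band for per-frame mean articular distance, mm (strict).
PENETRATION_LIMIT_MM = -0.5
GAP_LIMIT_MM = 1.5


@dataclass
class DistanceMap:
    """Per-vertex signed articular distances (mm) at one frame."""

    distances_mm: np.ndarray
    frame_index: int = 0

    def __post_init__(self):
        self.distances_mm = np.asarray(self.distances_mm, dtype=float).reshape(-1)
        if not np.all(np.isfinite(self.distances_mm)):
            raise ValueError("distance map contains non-finite values")

    @property
    def mean(self) -> float:
        return float(self.distances_mm.mean())

    @property
    def min(self) -> float:
        return float(self.distances_mm.min())

    @property
    def max(self) -> float:
        return float(self.distances_mm.max())

    def passes_band(self, penetration_mm: float = PENETRATION_LIMIT_MM,
                    gap_mm: float = GAP_LIMIT_MM) -> bool:
        """Strict band test on the per-frame mean distance."""
        return penetration_mm < self.mean < gap_mm


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

def closest_point_distance(points: np.ndarray, mesh: trimesh.Trimesh,
                           chunk: int = 512) -> np.ndarray:
    """Unsigned distance from each point to the mesh surface.

    Exact point-triangle distances (Ericson's region classification),
    vectorized over (point, triangle) blocks.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    tris = mesh.triangles
    best = np.full(len(pts), np.inf)
    for t0 in range(0, len(tris), chunk):
        T = tris[t0:t0 + chunk]
        d2 = _point_triangle_sqdist(pts, T)
        best = np.minimum(best, d2.min(axis=1))
    return np.sqrt(best)


def _segment_sqdist(P, A, B):
    """Squared distance from points (n,1,3) to segments (1,m,3)-(1,m,3)."""
    ab = B - A
    t = ((P - A) * ab).sum(-1) / np.maximum((ab * ab).sum(-1), 1e-300)
    t = np.clip(t, 0.0, 1.0)
    diff = P - (A + t[..., None] * ab)
    return (diff * diff).sum(-1)


def _point_triangle_sqdist(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Squared distances, shape (n_points, n_tris).

    Minimum over the three clamped edge distances and, where the plane
    projection falls inside the triangle, the plane distance — exact and
    order-independent.
    """
    A = tris[:, 0][None, :, :]  # (1, m, 3)
    B = tris[:, 1][None, :, :]
    C = tris[:, 2][None, :, :]
    P = points[:, None, :]      # (n, 1, 3)

    d2 = np.minimum(_segment_sqdist(P, A, B), _segment_sqdist(P, A, C))
    d2 = np.minimum(d2, _segment_sqdist(P, B, C))

    ab = B - A
    ac = C - A
    n = np.cross(ab, ac)
    nn = (n * n).sum(-1)
    ap = P - A
    dist_plane = (ap * n).sum(-1)
    # barycentric coordinates of the plane projection
    proj = ap - (dist_plane / np.maximum(nn, 1e-300))[..., None] * n
    d00 = (ab * ab).sum(-1)
    d01 = (ab * ac).sum(-1)
    d11 = (ac * ac).sum(-1)
    pv0 = (proj * ab).sum(-1)
    pv1 = (proj * ac).sum(-1)
    denom = np.maximum(d00 * d11 - d01 * d01, 1e-300)
    v = (d11 * pv0 - d01 * pv1) / denom
    w = (d00 * pv1 - d01 * pv0) / denom
    inside = (v >= 0) & (w >= 0) & (v + w <= 1) & (nn > 0)
    plane_sq = dist_plane * dist_plane / np.maximum(nn, 1e-300)
    return np.where(inside, np.minimum(d2, plane_sq), d2)


def points_in_mesh(mesh: trimesh.Trimesh, points: np.ndarray,
                   chunk: int = 256) -> np.ndarray:
    """Watertight containment by vertical-ray crossing parity."""
    pts = np.atleast_2d(np.asarray(points, float)).copy()
    scale = float(np.abs(mesh.bounds).max()) or 1.0
    pts[:, 0] += 1.03e-9 * scale
    pts[:, 1] += 2.17e-9 * scale
    tris = mesh.triangles
    above = np.zeros(len(pts), dtype=np.int64)
    for t0 in range(0, len(tris), chunk):
        T = tris[t0:t0 + chunk]
        A, B, C = T[:, 0], T[:, 1], T[:, 2]
        v0 = (B - A)[None, :, :2]
        v1 = (C - A)[None, :, :2]
        denom = v0[..., 0] * v1[..., 1] - v0[..., 1] * v1[..., 0]
        ok = np.abs(denom) > 1e-14
        w = pts[:, None, :2] - A[None, :, :2]
        u = (w[..., 0] * v1[..., 1] - w[..., 1] * v1[..., 0]) / np.where(ok, denom, 1.0)
        v = (v0[..., 0] * w[..., 1] - v0[..., 1] * w[..., 0]) / np.where(ok, denom, 1.0)
        hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1)
        zhit = (A[None, :, 2] + u * (B - A)[None, :, 2] + v * (C - A)[None, :, 2])
        above += np.sum(hit & (zhit > pts[:, None, 2]), axis=1)
    return (above % 2) == 1


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def place_polymer(tibial_hybrid_pose: Pose, polymer_mesh: trimesh.Trimesh,
                  polymer_link: RigidTransform) -> trimesh.Trimesh:
    """Polymer insert carried rigidly with the tracked tibial hybrid model.

    Vertices are mapped by ``tibial_pose ∘ polymer_link`` (fixed-bearing
    attachment: the insert never moves relative to the tray).
    """
    total = compose(tibial_hybrid_pose.transform, polymer_link)
    placed = polymer_mesh.copy()
    placed.apply_transform(total.matrix)
    return placed


def signed_distance(source_patch: np.ndarray, target_mesh: trimesh.Trimesh,
                    frame_index: int = 0) -> DistanceMap:
    """Signed closest-point distances from patch vertices to a mesh.

    Negative where the vertex lies inside the (watertight) target volume
    — articular penetration — positive in a gap.
    """
    if not target_mesh.is_watertight:
        raise ValueError("target mesh is not watertight: distance sign undefined")
    pts = np.atleast_2d(np.asarray(source_patch, float))
    d = closest_point_distance(pts, target_mesh)
    inside = points_in_mesh(target_mesh, pts)
    d[inside] *= -1.0
    return DistanceMap(d, frame_index)


def save_distance_ply(points: np.ndarray, distance_map: DistanceMap,
                      path) -> None:
    """Write patch vertices with their signed distance as an ASCII PLY
    point cloud (scalar in the ``quality`` property)."""
    pts = np.atleast_2d(np.asarray(points, float))
    d = distance_map.distances_mm
    if len(pts) != d.size:
        raise ValueError("vertex count does not match the distance map")
    lines = ["ply", "format ascii 1.0",
             f"element vertex {len(pts)}",
             "property float x", "property float y", "property float z",
             "property float quality", "end_header"]
    for (x, y, z), q in zip(pts, d):
        lines.append(f"{x:.6f} {y:.6f} {z:.6f} {q:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def maps_to_csv(maps: list[DistanceMap], path) -> None:
    """Per-frame summary table: frame, mean/min/max distance, band pass."""
    import pandas as pd
    rows = [{"frame": m.frame_index, "mean_mm": m.mean, "min_mm": m.min,
             "max_mm": m.max, "pass": m.passes_band()} for m in maps]
    pd.DataFrame(rows).to_csv(path, index=False)


def trial_summary(maps: list[DistanceMap],
                  penetration_mm: float = PENETRATION_LIMIT_MM,
                  gap_mm: float = GAP_LIMIT_MM) -> dict:
    """Whole-trial verification report over per-frame distance maps.

    The acceptance band gates each frame's *mean* distance (strict
    inequalities); per-vertex extremes are reported but not gating.
    """
    if not maps:
        raise ValueError("no distance maps to summarize")
    frame_means = np.array([m.mean for m in maps])
    passes = [m.passes_band(penetration_mm, gap_mm) for m in maps]
    report = {
        "trial_mean_mm": float(frame_means.mean()),
        "trial_pass": bool(all(passes)),
        "band_mm": [penetration_mm, gap_mm],
        "n_frames": len(maps),
        "frames": [
            {"frame": m.frame_index, "mean_mm": m.mean, "min_mm": m.min,
             "max_mm": m.max, "pass": bool(p)}
            for m, p in zip(maps, passes)
        ],
        "heel_strike": {"frame": maps[0].frame_index, "mean_mm": maps[0].mean,
                        "min_mm": maps[0].min, "max_mm": maps[0].max},
        "toe_off": {"frame": maps[-1].frame_index, "mean_mm": maps[-1].mean,
                    "min_mm": maps[-1].min, "max_mm": maps[-1].max},
        "min_mm": float(min(m.min for m in maps)),
        "max_mm": float(max(m.max for m in maps)),
    }
    return report
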