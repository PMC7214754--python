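"""Watertight parametric mesh primitives for the phantom.

Vendor implant CAD is proprietary, so the phantom uses millimetre-scale
parametric stand-ins built from extruded 2-D profiles: a tibial tray as a
plate-plus-keel T-profile, a polymer insert as a slab with a cylindrically
concave inferior face, and a talar dome as cylinder segments.  Profiles are
triangulated by ear clipping (simple CCW polygons, no holes) and extruded
with configurable intermediate layers so articular faces carry a dense
vertex grid for distance mapping.
"""

from __future__ import annotations

import numpy as np
import trimesh

__all__ = ["triangulate_simple_polygon", "extrude_profile", "tube_mesh",
           "cylinder_segment_profile", "concave_slab_profile"]


def _cross(o, a, b):
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def triangulate_simple_polygon(pts: np.ndarray) -> list[tuple[int, int, int]]:
    """Ear-clipping triangulation of a simple CCW polygon (no holes)."""
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    if n < 3:
        raise ValueError("polygon needs at least 3 vertices")
    area2 = sum(_cross(pts[0], pts[i], pts[i + 1]) for i in range(1, n - 1))
    if area2 <= 0:
        raise ValueError("polygon must be counter-clockwise and non-degenerate")
    scale = float(np.abs(pts).max()) or 1.0
    eps = 1e-12 * scale * scale
    idx = list(range(n))
    tris: list[tuple[int, int, int]] = []
    while len(idx) > 3:
        m = len(idx)
        for k in range(m):
            i0, i1, i2 = idx[k - 1], idx[k], idx[(k + 1) % m]
            a, b, c = pts[i0], pts[i1], pts[i2]
            if _cross(a, b, c) <= eps:
                continue  # reflex or collinear corner: not an ear
            contains_other = False
            for j in idx:
                if j in (i0, i1, i2):
                    continue
                p = pts[j]
                if (_cross(a, b, p) >= -eps and _cross(b, c, p) >= -eps
                        and _cross(c, a, p) >= -eps):
                    contains_other = True
                    break
            if not contains_other:
                tris.append((i0, i1, i2))
                idx.pop(k)
                break
        else:
            raise ValueError("ear clipping failed: polygon may self-intersect")
    tris.append(tuple(idx))
    return tris


_AXIS_MAP = {
    # profile (a, b) + extrusion coordinate c -> world (x, y, z)
    "z": lambda a, b, c: np.stack([a, b, c], axis=-1),
    "y": lambda a, b, c: np.stack([a, c, b], axis=-1),
    "x": lambda a, b, c: np.stack([c, a, b], axis=-1),
}


def extrude_profile(profile: np.ndarray, c0: float, c1: float,
                    axis: str = "z", n_layers: int = 2) -> trimesh.Trimesh:
    """Extrude a simple CCW 2-D profile along one world axis.

    ``n_layers ≥ 2`` vertex rings are placed between ``c0`` and ``c1`` so
    the side walls are subdivided along the extrusion direction.
    """
    profile = np.asarray(profile, dtype=float)
    if c1 <= c0:
        raise ValueError("extrusion interval must have c1 > c0")
    n = len(profile)
    cap = triangulate_simple_polygon(profile)
    levels = np.linspace(c0, c1, max(2, int(n_layers)))
    nl = len(levels)
    to_world = _AXIS_MAP[axis]
    verts = np.concatenate([
        to_world(profile[:, 0], profile[:, 1], np.full(n, lev)) for lev in levels
    ])
    faces = []
    for l in range(nl - 1):
        base0, base1 = l * n, (l + 1) * n
        for i in range(n):
            j = (i + 1) % n
            faces.append((base0 + i, base0 + j, base1 + j))
            faces.append((base0 + i, base1 + j, base1 + i))
    top = (nl - 1) * n
    for (i0, i1, i2) in cap:
        faces.append((i0, i2, i1))                 # bottom cap, reversed
        faces.append((top + i0, top + i1, top + i2))  # top cap
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise ValueError("extrusion produced a non-watertight mesh")
    return mesh


def tube_mesh(r_outer: float, r_inner: float, z0: float, z1: float,
              sections: int = 48, n_layers: int = 2,
              center_xy=(0.0, 0.0)) -> trimesh.Trimesh:
    """Hollow cylinder (cortical-shell solid) along z with annular caps."""
    if not (0 < r_inner < r_outer):
        raise ValueError("need 0 < r_inner < r_outer")
    th = np.linspace(0, 2 * np.pi, sections, endpoint=False)
    cx, cy = center_xy
    ring_o = np.stack([cx + r_outer * np.cos(th), cy + r_outer * np.sin(th)], axis=1)
    ring_i = np.stack([cx + r_inner * np.cos(th), cy + r_inner * np.sin(th)], axis=1)
    levels = np.linspace(z0, z1, max(2, int(n_layers)))
    nl, n = len(levels), sections
    verts = []
    for lev in levels:
        verts.append(np.column_stack([ring_o, np.full(n, lev)]))
    for lev in levels:
        verts.append(np.column_stack([ring_i, np.full(n, lev)]))
    verts = np.concatenate(verts)
    inner0 = nl * n
    faces = []
    for l in range(nl - 1):
        for i in range(n):
            j = (i + 1) % n
            a0, a1 = l * n, (l + 1) * n
            faces.append((a0 + i, a0 + j, a1 + j))      # outer wall, outward
            faces.append((a0 + i, a1 + j, a1 + i))
            b0, b1 = inner0 + l * n, inner0 + (l + 1) * n
            faces.append((b0 + i, b1 + j, b0 + j))      # inner wall, inward
            faces.append((b0 + i, b1 + i, b1 + j))
    topo = (nl - 1) * n
    topi = inner0 + (nl - 1) * n
    for i in range(n):
        j = (i + 1) % n
        faces.append((i, inner0 + j, inner0 + i))       # bottom annulus
        faces.append((i, j, inner0 + j))
        faces.append((topo + i, topi + i, topi + j))    # top annulus
        faces.append((topo + i, topi + j, topo + j))
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise ValueError("tube construction produced a non-watertight mesh")
    return mesh


def cylinder_segment_profile(radius: float, apex: float, chord: float,
                             arc_points: int = 33) -> np.ndarray:
    """CCW profile of a circular segment in (u, v): arc apex at v=``apex``,
    flat chord at v=``chord``.  The arc center sits at (0, apex − radius)."""
    if not (chord < apex <= chord + radius + radius):
        raise ValueError("need chord < apex")
    vc = apex - radius
    h = apex - chord
    if h >= 2 * radius:
        raise ValueError("segment height must be below the diameter")
    half = np.sqrt(radius ** 2 - (chord - vc) ** 2)
    ang_half = np.arcsin(np.clip(half / radius, -1, 1))
    th = np.linspace(-ang_half, ang_half, arc_points)
    arc_u = radius * np.sin(th)
    arc_v = vc + radius * np.cos(th)
    # CCW: chord left->right, then arc right->left (excluding duplicated ends)
    pts = [(-half, chord), (half, chord)]
    for u, v in zip(arc_u[::-1][1:-1], arc_v[::-1][1:-1]):
        pts.append((u, v))
    return np.asarray(pts)


def concave_slab_profile(half_width: float, top: float, arc_radius: float,
                         arc_center_v: float, arc_points: int = 33) -> np.ndarray:
    """CCW slab profile in (u, v) with a concave circular bottom face.

    The bottom edge follows the circle of ``arc_radius`` centered at
    (0, ``arc_center_v``) (below the slab), bulging upward into the slab;
    the top edge is flat at v=``top``.
    """
    half_ang = np.arcsin(np.clip(half_width / arc_radius, -1, 1))
    th = np.linspace(-half_ang, half_ang, arc_points)
    arc_u = arc_radius * np.sin(th)
    arc_v = arc_center_v + arc_radius * np.cos(th)
    if np.max(arc_v) >= top:
        raise ValueError("concave arc pierces the slab top face")
    pts = [(u, v) for u, v in zip(arc_u, arc_v)]  # left -> right along arc
    pts.append((half_width, top))
    pts.append((-half_width, top))
    return np.asarray(pts)
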