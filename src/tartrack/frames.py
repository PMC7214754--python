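"""Anatomical coordinate systems on the hybrid models.

Axes are derived from the implant articulation geometry rather than from
eroded bony landmarks: a cylinder fit to the articular surface curvature
gives the medial-lateral axis, a tibial-shaft cylinder or an
anterior/posterior landmark pair gives the second (temporary) axis, and
two successive cross products complete a mutually orthogonal triple.

Handedness follows the clinical convention of the method: left limbs carry
a left-handed basis, right limbs a right-handed one, with v_ML medial,
v_AP anterior and v_SI superior on both sides.  The cross products are
therefore evaluated with a *handed* cross (right-hand rule for right
limbs, negated for left limbs), which is what makes the same two formulas
produce anatomically oriented axes on either side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["Cylinder", "AnatomicalFrame", "DegenerateFitError",
           "fit_cylinder", "build_tibia_frame", "build_talus_frame"]


class DegenerateFitError(ValueError):
    """Raised when a point set cannot constrain a cylinder fit."""


@dataclass(frozen=True)
class Cylinder:
    """Least-squares cylinder: a point on the axis, unit direction, radius."""

    axis_point: np.ndarray
    axis_direction: np.ndarray
    radius: float
    rms_residual_mm: float

    def __post_init__(self):
        object.__setattr__(self, "axis_point",
                           np.asarray(self.axis_point, float).reshape(3))
        d = np.asarray(self.axis_direction, float).reshape(3)
        object.__setattr__(self, "axis_direction", d / np.linalg.norm(d))
        if self.radius <= 0:
            raise DegenerateFitError("cylinder radius must be positive")


@dataclass(frozen=True)
class AnatomicalFrame:
    """Origin plus medial-lateral / anterior-posterior / superior-inferior
    unit axes; ``side`` fixes the handedness (left → det −1)."""

    origin: np.ndarray
    v_ml: np.ndarray
    v_ap: np.ndarray
    v_si: np.ndarray
    side: str = "left"

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float).reshape(3))
        for name in ("v_ml", "v_ap", "v_si"):
            v = np.asarray(getattr(self, name), float).reshape(3)
            object.__setattr__(self, name, v)
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} is not unit norm")
        B = self.basis
        if np.max(np.abs(B.T @ B - np.eye(3))) > 1e-9:
            raise ValueError("anatomical axes are not mutually orthogonal")
        det = np.linalg.det(B)
        expected = -1.0 if self.side == "left" else 1.0
        if abs(det - expected) > 1e-9:
            raise ValueError(
                f"handedness mismatch: det={det:+.3f} for side={self.side!r}")

    @property
    def basis(self) -> np.ndarray:
        """3×3 matrix with columns (v_ML, v_AP, v_SI)."""
        return np.column_stack([self.v_ml, self.v_ap, self.v_si])

    @property
    def handedness(self) -> int:
        return 1 if self.side == "right" else -1


def handed_cross(u: np.ndarray, v: np.ndarray, side: str) -> np.ndarray:
    """Cross product under the side's handedness convention."""
    c = np.cross(u, v)
    return c if side == "right" else -c


# ---------------------------------------------------------------------------
# Cylinder fitting
# ---------------------------------------------------------------------------

def _direction_from_angles(theta: float, phi: float) -> np.ndarray:
    return np.array([np.sin(theta) * np.cos(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(theta)])


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(d, e1)


def fit_cylinder(points: np.ndarray, max_radius: float = 1e4) -> Cylinder:
    """Least-squares cylinder through a 3-D point cloud.

    Minimizes Σ (distance-to-axis − r)² over axis direction (spherical
    angles), axis offset in the plane normal to the axis, and radius.  The
    axis is initialized from the principal direction of the centered cloud.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[0] < 6:
        raise DegenerateFitError("cylinder fit needs at least 6 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, sv, Vt = np.linalg.svd(centered, full_matrices=False)
    if sv[0] < 1e-12 or sv[1] / sv[0] < 1e-9:
        raise DegenerateFitError("points are collinear or coincident")
    if sv[2] / sv[0] < 1e-9:
        raise DegenerateFitError("points are coplanar: cylinder unconstrained")
    def residuals(p):
        theta, phi, u, v, r = p
        d = _direction_from_angles(theta, phi)
        e1, e2 = _perp_basis(d)
        c = centroid + u * e1 + v * e2
        w = pts - c
        radial = np.linalg.norm(w - np.outer(w @ d, d), axis=1)
        return radial - r

    # A short patch can make the principal direction ambiguous, so seed the
    # solver from every principal direction and keep the best converged fit.
    sol = None
    for d0 in Vt:
        theta0 = float(np.arccos(np.clip(d0[2], -1, 1)))
        phi0 = float(np.arctan2(d0[1], d0[0]))
        radial0 = np.linalg.norm(centered - np.outer(centered @ d0, d0), axis=1)
        r0 = float(radial0.mean())
        cand = least_squares(residuals,
                             x0=[theta0, phi0, 0.0, 0.0, max(r0, 1e-3)],
                             method="lm", max_nfev=2000)
        if sol is None or cand.cost < sol.cost:
            sol = cand
    theta, phi, u, v, r = sol.x
    if not np.isfinite(r) or abs(r) > max_radius:
        raise DegenerateFitError("cylinder fit diverged (radius unbounded)")
    d = _direction_from_angles(theta, phi)
    e1, e2 = _perp_basis(d)
    c = centroid + u * e1 + v * e2
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return Cylinder(c, d, float(abs(r)), rms)


# ---------------------------------------------------------------------------
# Frame construction
# ---------------------------------------------------------------------------

def _axis_base(cyl: Cylinder, patch: np.ndarray, direction: np.ndarray
               ) -> np.ndarray:
    """Point on the cylinder axis at the patch extreme along ``direction``."""
    t = (np.atleast_2d(patch) - cyl.axis_point) @ direction
    return cyl.axis_point + float(t.max()) * direction


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateFitError("axes are parallel; frame undefined")
    return v / n


def build_tibia_frame(selections: dict, side: str = "left") -> AnatomicalFrame:
    """Tibial hybrid frame from articular and shaft cylinder fits.

    ``selections`` supplies (CT-space coordinates):

    * ``articular_patch`` — points on the distal articulating surface of
      the tibial component (v_ML from this cylinder's axis);
    * ``shaft_patch`` — points on the tibial shaft (temporary v_SI);
    * ``medial_edge_point`` — distal-medial implant edge, used only to
      orient v_ML medially;
    * ``implant_base_point`` — a point on the tibial implant's base plane,
      onto which the origin is translated along v_SI.

    The triple is completed by v_AP = cross_h(v_SI,temp, v_ML) and
    v_SI = cross_h(v_ML, v_AP) under the side's handedness.
    """
    art = np.atleast_2d(np.asarray(selections["articular_patch"], float))
    shaft = np.atleast_2d(np.asarray(selections["shaft_patch"], float))
    medial_pt = np.asarray(selections["medial_edge_point"], float).reshape(3)

    cyl_art = fit_cylinder(art)
    cyl_shaft = fit_cylinder(shaft)

    ml = cyl_art.axis_direction
    if (medial_pt - cyl_art.axis_point) @ ml < 0:
        ml = -ml
    si_temp = cyl_shaft.axis_direction
    # shaft axis points away from the joint (superior)
    if (shaft.mean(axis=0) - art.mean(axis=0)) @ si_temp < 0:
        si_temp = -si_temp
    ap = _normalize(handed_cross(si_temp, ml, side))
    si = handed_cross(ml, ap, side)

    base = _axis_base(cyl_art, art, ml)
    if "implant_base_point" in selections:
        base_point = np.asarray(selections["implant_base_point"],
                                float).reshape(3)
    else:
        base_point = np.asarray(_default_base_point(selections),
                                float).reshape(3)
    origin = base + ((base_point - base) @ si) * si
    return AnatomicalFrame(origin, ml, ap, si, side)


def _default_base_point(selections: dict):
    z = selections.get("implant_base_plane_z")
    if z is None:
        raise KeyError("selections need implant_base_point or implant_base_plane_z")
    return np.array([0.0, 0.0, float(z)])


def build_talus_frame(selections: dict, side: str = "left") -> AnatomicalFrame:
    """Talar hybrid frame from the dome cylinder fit and two splines.

    v_ML is parallel to the dome cylinder axis, carried by a line offset a
    quarter radius from the axis toward the implant base (the dome chord
    plane); the origin is that line's base at the patch's medial extreme.
    A temporary anterior-posterior direction joins the posterior and
    anterior spline centroids; v_SI = cross_h(v_ML, v_AP,temp) (oriented
    superior) and v_AP = cross_h(v_SI, v_ML) complete the triple.
    """
    dome = np.atleast_2d(np.asarray(selections["dome_patch"], float))
    ant = np.atleast_2d(np.asarray(selections["anterior_spline"], float))
    post = np.atleast_2d(np.asarray(selections["posterior_spline"], float))

    cyl = fit_cylinder(dome)
    ap_temp = _normalize(ant.mean(axis=0) - post.mean(axis=0))

    # superior hint: from the axis toward the articular patch (the dome
    # surface is proximal), which also points toward the chord plane
    centroid_offset = dome.mean(axis=0) - cyl.axis_point
    perp = centroid_offset - (centroid_offset @ cyl.axis_direction) * cyl.axis_direction
    superior_hint = _normalize(perp)

    ml = cyl.axis_direction
    si = handed_cross(ml, ap_temp, side)
    if si @ superior_hint < 0:
        ml = -ml
        si = handed_cross(ml, ap_temp, side)
    si = _normalize(si)
    ap = handed_cross(si, ml, side)

    base = _axis_base(cyl, dome, ml) + 0.25 * cyl.radius * superior_hint
    return AnatomicalFrame(base, ml, ap, si, side)
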