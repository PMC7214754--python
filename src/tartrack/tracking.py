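"""Model-based tracking: 6-DOF pose optimization against biplane views.

Each candidate pose is scored by rendering the object's DRR volume into
both calibrated views and comparing Sobel edge images with the target
frames via normalized cross-correlation (edge NCC is invariant to the
synthetic intensity scale of the DRR).  A seeded multi-start
Nelder-Mead direct search over (tx, ty, tz, rx, ry, rz) — translations in
mm, rotations as small axis-angle increments composed onto the
initialization about the object's center — refines the pose frame by
frame; sequences are tracked with warm starts from the previous solution.

The human 3-D review loop of the original workflow is replaced by
automated convergence/review flags and a machine-readable review report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import minimize
from skimage.filters import sobel

from .drr import DRRVolume
from .geometry import Pose, RigidTransform
from .projection import CameraModel, project_volume

__all__ = ["TrackingResult", "TrackingError", "CompoundDRR", "sobel_edges",
           "project_drr", "pose_cost", "track_frame", "track_sequence",
           "REVIEW_COST_THRESHOLD"]

#: Final cost above this raises the manual-review flag.
REVIEW_COST_THRESHOLD = 0.35
#: Cost improvement below this over a polish pass marks convergence.
CONVERGENCE_TOL = 1e-6


class TrackingError(RuntimeError):
    """Raised for non-finite costs or unusable tracking inputs."""


@dataclass
class TrackingResult:
    """Pose sequence with per-frame cost, convergence and review flags."""

    poses: list
    costs: np.ndarray
    converged: np.ndarray
    review_flags: np.ndarray

    def __post_init__(self):
        self.costs = np.asarray(self.costs, dtype=float)
        self.converged = np.asarray(self.converged, dtype=bool)
        self.review_flags = np.asarray(self.review_flags, dtype=bool)
        if not np.all(np.isfinite(self.costs)):
            raise TrackingError("tracking produced non-finite costs")
        if not (len(self.poses) == self.costs.size == self.converged.size
                == self.review_flags.size):
            raise ValueError("per-frame arrays have mismatched lengths")

    def review_report(self) -> dict:
        """Frames whose solution needs a second look (stands in for the
        interactive 3-D visual check)."""
        flagged = np.nonzero(self.review_flags)[0]
        return {
            "n_frames": len(self.poses),
            "n_flagged": int(flagged.size),
            "flagged_frames": [int(i) for i in flagged],
            "max_cost": float(self.costs.max()),
            "mean_cost": float(self.costs.mean()),
        }

    def to_csv(self, path) -> None:
        rows = []
        for p, c, conv, rev in zip(self.poses, self.costs, self.converged,
                                   self.review_flags):
            rows.append([p.frame_index, p.timestamp, *p.translation,
                         *p.rotation.reshape(-1), c, bool(conv), bool(rev)])
        cols = ["frame", "time_s", "tx", "ty", "tz",
                "r00", "r01", "r02", "r10", "r11", "r12", "r20", "r21", "r22",
                "cost", "converged", "review"]
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Image operations
# ---------------------------------------------------------------------------

def sobel_edges(image: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude, normalized to [0, 1]."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("edge detection needs a 2-D image of at least 3x3")
    mag = sobel(image)
    peak = mag.max()
    return mag / peak if peak > 0 else mag


def project_drr(drr, pose: Pose | RigidTransform | None,
                camera: CameraModel, window=None,
                step_mm: float | None = None) -> np.ndarray:
    """Perspective line-integral projection of a posed (compound) DRR."""
    transform = pose.transform if isinstance(pose, Pose) else pose
    if isinstance(drr, CompoundDRR):
        img = None
        for comp, offset in drr.components:
            t = transform if offset is None else _chain(transform, offset)
            part = project_volume(comp.intensities, comp.grid, t, camera,
                                  window=window, step_mm=step_mm)
            img = part if img is None else img + part
        return img
    return project_volume(drr.intensities, drr.grid, transform, camera,
                          window=window, step_mm=step_mm)


def _chain(outer: RigidTransform | None, inner: RigidTransform) -> RigidTransform:
    if outer is None:
        return inner
    return RigidTransform(outer.rotation @ inner.rotation,
                          outer.rotation @ inner.translation + outer.translation,
                          inner.source_space, outer.target_space)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


class CompoundDRR:
    """A rigid body renderable as several component volumes.

    Each component is a ``(DRRVolume, offset)`` pair where ``offset`` maps
    the component's own grid coordinates into the body's model space
    (``None`` = identity).  Projections are the sum of the components'
    line integrals, so an implant can stay on its own fine CAD grid
    instead of being resampled onto the bone grid — the rendered
    silhouette keeps sub-CT-voxel boundary fidelity.
    """

    def __init__(self, components):
        self.components = [(drr, off) for drr, off in components]
        if not self.components:
            raise ValueError("compound DRR needs at least one component")

    def support_centroid(self) -> np.ndarray:
        """Intensity-weighted centroid in model space (for pivot choice)."""
        total_w = 0.0
        acc = np.zeros(3)
        for drr, off in self.components:
            sup = np.nonzero(drr.intensities)
            if not sup[0].size:
                continue
            w = float(np.abs(drr.intensities[sup]).sum())
            c = drr.grid.voxel_to_world(
                np.mean(np.stack(sup, axis=1), axis=0))[0]
            if off is not None:
                c = off.apply(c)
            acc += w * c
            total_w += w
        return acc / total_w if total_w else acc


def _roi_window(mask: np.ndarray) -> tuple:
    """Bounding-box (row, col) slices of a boolean attention mask."""
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    if rows.size == 0:
        return (slice(0, mask.shape[0]), slice(0, mask.shape[1]))
    return (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))


def roi_masks(drr: DRRVolume, pose: Pose | RigidTransform, cameras,
              dilate_px: int = 12) -> list[np.ndarray]:
    """Per-view attention windows: the model's projected footprint at the
    given (initialization) pose, dilated to cover the capture range.

    Windowing the cost to this fixed region suppresses edges of *other*
    objects in the scene — the automated counterpart of the operator
    concentrating on one structure during semi-automated tracking.
    """
    masks = []
    for cam in cameras:
        # footprint only: a coarse ray step is plenty
        footprint = project_drr(drr, pose, cam, step_mm=2.5) > 0
        masks.append(ndimage.binary_dilation(
            footprint, iterations=dilate_px))
    return masks


def pose_cost(pose: Pose | RigidTransform, drr: DRRVolume,
              images, cameras, rois=None, _target_edges=None,
              step_mm: float | None = None) -> float:
    """1 − mean edge-NCC over the two views; in [0, 2], lower is better.

    ``rois`` optionally restricts the correlation to per-view attention
    windows (boolean masks); ``step_mm`` overrides the ray sampling step.
    """
    if len(images) != 2 or len(cameras) != 2:
        raise ValueError("pose cost is defined for exactly two views")
    if _target_edges is None:
        _target_edges = [sobel_edges(im) for im in images]
    score = 0.0
    for i, (cam, tgt) in enumerate(zip(cameras, _target_edges)):
        if rois is not None:
            m = rois[i]
            win = _roi_window(m)
            rendered = sobel_edges(project_drr(drr, pose, cam, window=win,
                                               step_mm=step_mm))
            score += _ncc(rendered[m[win]], tgt[win][m[win]])
        else:
            rendered = sobel_edges(project_drr(drr, pose, cam, step_mm=step_mm))
            score += _ncc(rendered, tgt)
    cost = 1.0 - score / 2.0
    if not np.isfinite(cost):
        raise TrackingError("pose cost is not finite")
    return cost


# ---------------------------------------------------------------------------
# Frame and sequence tracking
# ---------------------------------------------------------------------------

def _rotvec_matrix(rotvec_deg: np.ndarray) -> np.ndarray:
    angle = np.linalg.norm(rotvec_deg)
    if angle < 1e-12:
        return np.eye(3)
    axis = rotvec_deg / angle
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    t = np.radians(angle)
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * K @ K


def _perturbed_pose(params: np.ndarray, init: RigidTransform,
                    center: np.ndarray) -> RigidTransform:
    """Apply (tx, ty, tz, rx, ry, rz) increments onto the init pose,
    rotating about the object's world-space center."""
    dR = _rotvec_matrix(params[3:])
    R = dR @ init.rotation
    t = dR @ (init.translation - center) + center + params[:3]
    return RigidTransform(R, t, init.source_space, init.target_space)


def track_frame(drr: DRRVolume, images, cameras, init: Pose,
                seed: int = 0, n_restarts: int = 2,
                max_evals: int = 220, simplex_step: float = 1.0,
                restart_translation_mm: float = 1.5,
                restart_rotation_deg: float = 1.5,
                review_threshold: float = REVIEW_COST_THRESHOLD,
                use_roi: bool = True, roi_dilate_px: int = 12,
                roi_exclude=None, capture_range=(6.0, 6.0),
                step_mm: float | None = None
                ) -> tuple[Pose, float, dict]:
    """Optimize one frame's 6-DOF pose from a biplane image pair.

    The initialization must lie within the tracker's capture range
    (≲5 mm / 5°); ``capture_range`` (mm, deg) turns that precondition into
    a soft quadratic penalty so near-symmetric objects cannot escape to a
    distant self-similar basin.  Returns ``(pose, cost, flags)`` where
    flags carry ``converged`` and ``review``.
    """
    target_edges = [sobel_edges(im) for im in images]
    rois = (roi_masks(drr, init.transform, cameras, roi_dilate_px)
            if use_roi else None)
    if rois is not None and roi_exclude is not None:
        rois = [r & ~ex for r, ex in zip(rois, roi_exclude)]
        if any(r.sum() < 64 for r in rois):
            raise TrackingError("attention window nearly empty after "
                                "exclusion masking")
    if isinstance(drr, CompoundDRR):
        centroid_model = drr.support_centroid()
    else:
        support = np.nonzero(drr.intensities)
        if support[0].size:
            centroid_model = drr.grid.voxel_to_world(
                np.mean(np.stack(support, axis=1), axis=0))[0]
        else:
            centroid_model = drr.grid.voxel_to_world(
                [np.array(drr.grid.shape) / 2.0])[0]
    center = init.transform.apply(centroid_model)

    t_bound, r_bound = capture_range

    def fun(p):
        cost = pose_cost(_perturbed_pose(p, init.transform, center),
                         drr, images, cameras, rois=rois,
                         _target_edges=target_edges, step_mm=step_mm)
        excess = (np.maximum(np.abs(p[:3]) - t_bound, 0.0).sum()
                  + np.maximum(np.abs(p[3:]) - r_bound, 0.0).sum())
        return cost + 0.2 * excess ** 2

    rng = np.random.default_rng(seed)
    best = None
    start = np.zeros(6)
    for attempt in range(1 + n_restarts):
        res = minimize(fun, start, method="Nelder-Mead",
                       options={"maxfev": max_evals, "xatol": 5e-3,
                                "fatol": CONVERGENCE_TOL, "adaptive": True,
                                "initial_simplex": _initial_simplex(
                                    start, simplex_step)})
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < review_threshold:
            break
        start = np.concatenate([
            rng.uniform(-restart_translation_mm, restart_translation_mm, 3),
            rng.uniform(-restart_rotation_deg, restart_rotation_deg, 3)])
    pose = Pose(_perturbed_pose(best.x, init.transform, center),
                frame_index=init.frame_index,
                frame_rate_hz=init.frame_rate_hz)
    flags = {"converged": bool(best.success or best.fun < review_threshold),
             "review": bool(best.fun > review_threshold)}
    return pose, float(best.fun), flags


def _initial_simplex(start: np.ndarray, step: float = 1.0) -> np.ndarray:
    simplex = np.tile(start, (7, 1))
    for i in range(6):
        simplex[i + 1, i] += step  # mm / deg
    return simplex


def track_sequence(drr: DRRVolume, sequences, cameras, init: Pose,
                   seed: int = 0, **frame_kwargs) -> TrackingResult:
    """Track a biplane image sequence; frame t warm-starts from t−1.

    ``sequences`` is a pair of image stacks (n_frames, rows, cols), one
    per camera.
    """
    stack1, stack2 = sequences
    n = len(stack1)
    if n == 0:
        raise ValueError("empty image sequence")
    if len(stack2) != n:
        raise ValueError("the two view sequences differ in length")
    frame_kwargs.setdefault("max_evals", 150)
    poses, costs, conv, review = [], [], [], []
    current = init
    for i in range(n):
        if i == 1:
            frame_kwargs.setdefault("simplex_step", 0.6)
        current = Pose(current.transform, frame_index=i,
                       frame_rate_hz=init.frame_rate_hz)
        pose, cost, flags = track_frame(
            drr, (stack1[i], stack2[i]), cameras, current,
            seed=seed + i, **frame_kwargs)
        poses.append(pose)
        costs.append(cost)
        conv.append(flags["converged"])
        review.append(flags["review"])
        current = pose
    return TrackingResult(poses, np.array(costs), np.array(conv),
                          np.array(review))


# ---------------------------------------------------------------------------
# Multi-object tracking on residual images
# ---------------------------------------------------------------------------

def _fit_view_scales(target: np.ndarray, projections: list[np.ndarray]
                     ) -> np.ndarray:
    """Least-squares intensity scales matching rendered models to one view."""
    A = np.stack([p.reshape(-1) for p in projections], axis=1)
    coef, *_ = np.linalg.lstsq(A, target.reshape(-1), rcond=None)
    return np.clip(coef, 0.0, None)


def track_frame_multi(objects: dict, images, cameras, inits: dict,
                      seed: int = 0, sweeps: int = 2,
                      polish_evals: int = 100, **frame_kwargs) -> dict:
    """Alternating 6-DOF refinement of several rigid objects in one frame.

    Biplane images are sums of overlapping projections, so tracking one
    structure against the raw frames is biased wherever another structure's
    edges fall nearby (bone rim vs. tray edge, dome vs. insert).  Here each
    object is optimized against *residual* images: the other objects,
    rendered from their ``render`` volumes at their current pose estimates
    and intensity-scaled per view by least squares, are subtracted from the
    target first.  Sweeping the object set a couple of times converges the
    joint solution — the automated counterpart of an operator refining
    structures one at a time.

    ``objects`` maps name → ``{"drr": DRRVolume (matched), "render":
    DRRVolume (subtracted), "exclude": [names]}``; ``inits`` maps name →
    Pose.  An object's optional ``exclude`` list removes the dilated
    projected footprints of the named objects from its attention window —
    used to keep artifact-degraded bone regions next to metal out of the
    bone cost.
    """
    names = list(objects)
    est = {n: inits[n] for n in names}
    results = {}
    for sweep in range(sweeps):
        # per-view intensity scales for the render models at current poses
        proj = {n: [project_drr(objects[n]["render"], est[n], cam)
                    for cam in cameras] for n in names}
        scales = [
            _fit_view_scales(images[v], [proj[n][v] for n in names])
            for v in range(len(cameras))]
        kwargs = dict(frame_kwargs)
        if sweep > 0:
            # later sweeps polish an already-close solution
            kwargs["max_evals"] = min(kwargs.get("max_evals", 150), polish_evals)
            kwargs.setdefault("simplex_step", 0.4)
        for i, name in enumerate(names):
            residual = []
            exclude = None
            excl_names = objects[name].get("exclude") or []
            if excl_names:
                exclude = []
            for v, img in enumerate(images):
                others = sum(scales[v][j] * proj[n2][v]
                             for j, n2 in enumerate(names) if n2 != name)
                residual.append(img - others)
                if excl_names:
                    footprint = np.zeros(img.shape, dtype=bool)
                    for n2 in excl_names:
                        footprint |= proj[n2][v] > 0
                    exclude.append(ndimage.binary_dilation(
                        footprint, iterations=6))
            pose, cost, flags = track_frame(
                objects[name]["drr"], residual, cameras, est[name],
                seed=seed + 31 * sweep + i, roi_exclude=exclude, **kwargs)
            est[name] = pose
            results[name] = (pose, cost, flags)
    return results


def register_static_multi(objects: dict, frames, cameras, inits: dict,
                          seed: int = 0, sweeps: int = 2,
                          max_failure_fraction: float = 0.5,
                          **frame_kwargs) -> dict:
    """Mean static poses of several objects over the static-trial frames.

    Runs :func:`track_frame_multi` per frame (warm-started) and averages
    each object's per-frame poses into its mean static definition.
    """
    from .geometry import average_poses
    if not 1 <= len(frames) <= 20:
        raise ValueError("static registration expects 1-20 frame pairs")
    per_object = {n: [] for n in objects}
    flags_count = {n: 0 for n in objects}
    est = dict(inits)
    for f, pair in enumerate(frames):
        results = track_frame_multi(objects, pair, cameras, est,
                                    seed=seed + 1000 * f, sweeps=sweeps,
                                    **frame_kwargs)
        for n, (pose, _cost, flag) in results.items():
            per_object[n].append(pose)
            flags_count[n] += int(flag["review"])
            est[n] = pose
    means = {}
    for n, poses in per_object.items():
        if flags_count[n] / len(poses) > max_failure_fraction:
            from .hybrid import StaticTrackingError  # noqa: avoid cycle at import time
            raise StaticTrackingError(
                f"object {n!r}: {flags_count[n]}/{len(poses)} static frames "
                "failed tracking")
        means[n] = average_poses(poses)
    return means


def _extrapolate(previous: RigidTransform, current: RigidTransform
                 ) -> RigidTransform:
    """Constant-velocity pose prediction: apply the last world-frame
    increment once more."""
    dR = current.rotation @ previous.rotation.T
    dt = current.translation - dR @ previous.translation
    R = dR @ current.rotation
    U, _s, Vt = np.linalg.svd(R)  # polish to exact orthonormality
    return RigidTransform(U @ Vt, dR @ current.translation + dt,
                          current.source_space, current.target_space)


def track_sequence_multi(objects: dict, sequences, cameras, inits: dict,
                         seed: int = 0, sweeps: int = 2,
                         **frame_kwargs) -> dict:
    """Track several rigid objects through a biplane sequence jointly.

    Frame t warm-starts every object with a constant-velocity prediction
    from its t−1 and t−2 solutions (plain warm start for the first two
    frames); within a frame the objects alternate on residual images in
    the caller's dict order.  Returns name → :class:`TrackingResult`.
    """
    stack1, stack2 = sequences
    n = len(stack1)
    if n == 0:
        raise ValueError("empty image sequence")
    frame_kwargs.setdefault("max_evals", 150)
    prev: dict | None = None
    prev2: dict | None = None
    acc = {name: ([], [], [], []) for name in objects}
    for i in range(n):
        if i == 1:
            frame_kwargs.setdefault("simplex_step", 0.6)
        if prev is None:
            est = {n2: Pose(p.transform, i, p.frame_rate_hz)
                   for n2, p in inits.items()}
        elif prev2 is None:
            est = {n2: Pose(p.transform, i, p.frame_rate_hz)
                   for n2, p in prev.items()}
        else:
            est = {n2: Pose(_extrapolate(prev2[n2].transform,
                                         prev[n2].transform),
                            i, prev[n2].frame_rate_hz)
                   for n2 in prev}
        results = track_frame_multi(objects, (stack1[i], stack2[i]), cameras,
                                    est, seed=seed + 1000 * i, sweeps=sweeps,
                                    **frame_kwargs)
        prev2 = prev
        prev = {}
        for name, (pose, cost, flags) in results.items():
            poses, costs, conv, review = acc[name]
            poses.append(pose)
            costs.append(cost)
            conv.append(flags["converged"])
            review.append(flags["review"])
            prev[name] = pose
    return {name: TrackingResult(p, np.array(c), np.array(cv), np.array(rv))
            for name, (p, c, cv, rv) in acc.items()}
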