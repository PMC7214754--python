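"""Rigid transforms between the three coordinate domains of the tracking
workflow (CT/model space, global space, tracking space) and pose averaging.

The workflow manipulates three kinds of coordinate systems:

* **CT (model) space** — millimetre coordinates of a segmented volume or CAD
  mesh; each object's frame sits at the minimum corner of its bounding box
  with axes parallel to the grid, so its basis is the standard basis.
* **global space** — the standard basis ``{e_x, e_y, e_z}`` with origin 0.
* **MBT (tracking) space** — the laboratory frame of the biplane fluoroscopes
  in which tracked poses are expressed.

A transform between two frames ``A`` and ``B`` is the frame-alignment map
``T_A→B = F_B ∘ F_A⁻¹`` where ``F_X(x) = O_X + basis_Xᵀ x`` embeds
frame-local coordinates into the common world.  With the standard global
basis this reduces to the translation-difference / basis-projection recipe
used throughout the hybrid-model construction, and the CT→global rotation is
exactly the identity whenever the CT frame uses the standard basis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CoordinateFrame",
    "RigidTransform",
    "Pose",
    "InvalidFrameError",
    "ChainingError",
    "GLOBAL_FRAME",
    "transform_ct_to_global",
    "transform_global_to_mbt",
    "compose",
    "invert",
    "average_poses",
    "standard_frame",
    "poses_to_csv",
    "poses_from_csv",
]

_ORTHO_TOL = 1e-9

#: Default fluoroscopy frame rate, Hz.
FRAME_RATE_HZ = 200.0


class InvalidFrameError(ValueError):
    """Raised when a coordinate frame fails its orthonormality invariants."""


class ChainingError(ValueError):
    """Raised when transform space labels do not line up for composition."""


@dataclass(frozen=True)
class CoordinateFrame:
    """An origin plus three mutually orthogonal unit basis vectors.

    ``basis[i]`` is the i-th axis expressed in world coordinates (rows).
    Handedness (determinant ±1) is recorded, not forced: left-limb
    anatomical frames are deliberately left-handed.
    """

    origin: np.ndarray
    basis: np.ndarray
    label: str = "frame"

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        basis = np.asarray(self.basis, dtype=float).reshape(3, 3)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "basis", basis)
        norms = np.linalg.norm(basis, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise InvalidFrameError(f"basis vectors not unit norm: {norms}")
        gram = basis @ basis.T
        if np.max(np.abs(gram - np.eye(3))) > 1e-9:
            raise InvalidFrameError("basis vectors not mutually orthogonal")
        det = np.linalg.det(basis)
        if abs(abs(det) - 1.0) > 1e-9:
            raise InvalidFrameError(f"basis determinant {det} not ±1")

    @property
    def handedness(self) -> int:
        """+1 for a right-handed basis, −1 for left-handed."""
        return 1 if np.linalg.det(self.basis) > 0 else -1

    def embed(self, local_points: np.ndarray) -> np.ndarray:
        """Map frame-local coordinates into world coordinates."""
        pts = np.atleast_2d(np.asarray(local_points, dtype=float))
        return pts @ self.basis + self.origin


def standard_frame(origin=(0.0, 0.0, 0.0), label: str = "frame") -> CoordinateFrame:
    """Frame with the standard basis at ``origin`` (bounding-box-corner style)."""
    return CoordinateFrame(np.asarray(origin, dtype=float), np.eye(3), label)


GLOBAL_FRAME = standard_frame(label="global")


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid map ``x ↦ R x + t`` between two labelled spaces."""

    rotation: np.ndarray
    translation: np.ndarray
    source_space: str = "ct"
    target_space: str = "mbt"

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-9:
            raise InvalidFrameError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise InvalidFrameError("rotation determinant is not +1 (improper)")

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4×4 form ``[[R, t], [0, 1]]``."""
        T = np.eye(4)
        T[:3, :3] = self.rotation
        T[:3, 3] = self.translation
        return T

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.rotation.T + self.translation
        return out[0] if single else out

    @classmethod
    def identity(cls, source_space="ct", target_space="ct") -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), source_space, target_space)

    @classmethod
    def from_matrix(cls, T, source_space="ct", target_space="mbt") -> "RigidTransform":
        T = np.asarray(T, dtype=float).reshape(4, 4)
        return cls(T[:3, :3], T[:3, 3], source_space, target_space)

    def to_json(self) -> str:
        return json.dumps(
            {
                "matrix": self.matrix.reshape(-1).tolist(),
                "source_space": self.source_space,
                "target_space": self.target_space,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        d = json.loads(text)
        return cls.from_matrix(
            np.asarray(d["matrix"]).reshape(4, 4), d["source_space"], d["target_space"]
        )


@dataclass(frozen=True)
class Pose:
    """One object's rigid placement (model space → tracking space) at a frame."""

    transform: RigidTransform
    frame_index: int = 0
    frame_rate_hz: float = FRAME_RATE_HZ

    @property
    def timestamp(self) -> float:
        return self.frame_index / self.frame_rate_hz

    @property
    def rotation(self) -> np.ndarray:
        return self.transform.rotation

    @property
    def translation(self) -> np.ndarray:
        return self.transform.translation

    def apply(self, points) -> np.ndarray:
        return self.transform.apply(points)


def _frame_to_frame(source: CoordinateFrame, target: CoordinateFrame,
                    source_space: str, target_space: str) -> RigidTransform:
    # T = F_target ∘ F_source⁻¹ ; rotation targetᵀ·source, translation
    # O_target − R·O_source.  Requires proper rotation overall, so the two
    # frames must share handedness.
    if source.handedness != target.handedness:
        raise InvalidFrameError(
            "cannot build a rigid transform between frames of opposite handedness"
        )
    R = target.basis.T @ source.basis
    t = target.origin - R @ source.origin
    return RigidTransform(R, t, source_space, target_space)


def transform_ct_to_global(ct_frame: CoordinateFrame,
                           global_frame: CoordinateFrame = GLOBAL_FRAME) -> RigidTransform:
    """Transform from a CT-derived surface frame to the global frame.

    Translation is the origin difference; the rotation projects the global
    basis onto the CT basis and reduces exactly to the identity when the CT
    frame (a bounding-box frame) uses the standard basis.
    """
    return _frame_to_frame(ct_frame, global_frame, "ct", "global")


def transform_global_to_mbt(mbt_frame: CoordinateFrame) -> RigidTransform:
    """Transform from the global frame to a tracked (MBT) frame placement.

    The rotation's columns are the tracking-frame basis vectors expressed in
    global coordinates; the translation is the tracking-frame origin (the
    global origin being zero).
    """
    return _frame_to_frame(GLOBAL_FRAME, mbt_frame, "global", "mbt")


def compose(outer: RigidTransform, inner: RigidTransform) -> RigidTransform:
    """``outer · inner`` in homogeneous form, with space-label checking."""
    if inner.target_space != outer.source_space:
        raise ChainingError(
            f"cannot chain: inner targets '{inner.target_space}' but outer "
            f"sources '{outer.source_space}'"
        )
    R = outer.rotation @ inner.rotation
    t = outer.rotation @ inner.translation + outer.translation
    return RigidTransform(R, t, inner.source_space, outer.target_space)


def invert(T: RigidTransform) -> RigidTransform:
    """Inverse transform: rotation ``Rᵀ``, translation ``−Rᵀ t``, labels swapped."""
    Rt = T.rotation.T
    return RigidTransform(Rt, -Rt @ T.translation, T.target_space, T.source_space)


# ---------------------------------------------------------------------------
# Pose averaging (static trial)
# ---------------------------------------------------------------------------

def _rotation_to_quaternion(R: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) for a proper rotation matrix."""
    # Shepperd's method: pick the largest diagonal combination for stability.
    tr = np.trace(R)
    if tr > 0:
        s = np.sqrt(tr + 1.0) * 2.0
        return np.array([0.25 * s, (R[2, 1] - R[1, 2]) / s,
                         (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s])
    i = int(np.argmax(np.diag(R)))
    if i == 0:
        s = np.sqrt(1.0 + R[0, 0] - R[1, 1] - R[2, 2]) * 2.0
        q = [(R[2, 1] - R[1, 2]) / s, 0.25 * s,
             (R[0, 1] + R[1, 0]) / s, (R[0, 2] + R[2, 0]) / s]
    elif i == 1:
        s = np.sqrt(1.0 - R[0, 0] + R[1, 1] - R[2, 2]) * 2.0
        q = [(R[0, 2] - R[2, 0]) / s, (R[0, 1] + R[1, 0]) / s,
             0.25 * s, (R[1, 2] + R[2, 1]) / s]
    else:
        s = np.sqrt(1.0 - R[0, 0] - R[1, 1] + R[2, 2]) * 2.0
        q = [(R[1, 0] - R[0, 1]) / s, (R[0, 2] + R[2, 0]) / s,
             (R[1, 2] + R[2, 1]) / s, 0.25 * s]
    return np.asarray(q)


def _quaternion_to_rotation(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def rotation_angle_deg(R: np.ndarray) -> float:
    """Geodesic rotation angle of ``R`` in degrees."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def average_poses(poses: list[Pose]) -> Pose:
    """Mean static definition of a pose list.

    Translations are averaged arithmetically.  Rotations are averaged with
    the quaternion eigen-mean (principal eigenvector of the sum of
    sign-aligned quaternion outer products), then re-orthonormalized.  A
    warning is emitted when the rotations are spread more than 30° apart,
    which violates the static-trial assumption.
    """
    if not poses:
        raise ValueError("cannot average an empty pose list")
    spaces = {(p.transform.source_space, p.transform.target_space) for p in poses}
    if len(spaces) > 1:
        raise ChainingError(f"poses mix spaces: {spaces}")
    quats = np.stack([_rotation_to_quaternion(p.rotation) for p in poses])
    # Sign-align to the first quaternion (q and −q are the same rotation).
    signs = np.sign(quats @ quats[0])
    signs[signs == 0] = 1.0
    quats = quats * signs[:, None]

    angles = [rotation_angle_deg(p.rotation.T @ q.rotation)
              for p in poses for q in poses]
    if max(angles) > 30.0:
        warnings.warn(
            "pose rotations spread more than 30 degrees apart; static-trial "
            "assumption violated", stacklevel=2)

    M = np.einsum("ni,nj->ij", quats, quats)
    _, vecs = np.linalg.eigh(M)
    q_mean = vecs[:, -1]
    R = _quaternion_to_rotation(q_mean)
    # Polish orthonormality to the 1e-9 invariant.
    U, _, Vt = np.linalg.svd(R)
    R = U @ Vt
    t = np.mean([p.translation for p in poses], axis=0)
    src, tgt = next(iter(spaces))
    return Pose(RigidTransform(R, t, src, tgt),
                frame_index=poses[0].frame_index,
                frame_rate_hz=poses[0].frame_rate_hz)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_POSE_COLUMNS = ["frame", "time_s", "tx", "ty", "tz",
                 "r00", "r01", "r02", "r10", "r11", "r12", "r20", "r21", "r22"]


def poses_to_csv(poses: list[Pose], path) -> None:
    rows = []
    for p in poses:
        rows.append([p.frame_index, p.timestamp, *p.translation,
                     *p.rotation.reshape(-1)])
    pd.DataFrame(rows, columns=_POSE_COLUMNS).to_csv(path, index=False)


def poses_from_csv(path, source_space="ct", target_space="mbt",
                   frame_rate_hz: float = FRAME_RATE_HZ) -> list[Pose]:
    df = pd.read_csv(path)
    poses = []
    for _, row in df.iterrows():
        R = row[_POSE_COLUMNS[5:]].to_numpy(dtype=float).reshape(3, 3)
        t = row[["tx", "ty", "tz"]].to_numpy(dtype=float)
        poses.append(Pose(RigidTransform(R, t, source_space, target_space),
                          frame_index=int(row["frame"]),
                          frame_rate_hz=frame_rate_hz))
    return poses
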