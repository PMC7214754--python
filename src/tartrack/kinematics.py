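"""Joint-angle kinematics: Grood-Suntay decomposition, zero-phase
Butterworth filtering with residual-analysis cutoff selection, force-based
gait-event detection and percent-stance normalization.

Sign conventions (both limbs): dorsiflexion, inversion and internal
rotation are positive.  The joint coordinate system uses the tibial
medial-lateral axis as the first body-fixed axis, the talar
superior-inferior axis as the second, and their (normalized) cross product
as the floating axis; the decomposition is evaluated as an intrinsic
Cardan sequence in a right-handed working basis obtained by flipping the
ML axis of left-handed (left-limb) frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from .frames import AnatomicalFrame
from .geometry import Pose

__all__ = ["JointAngles", "GaitEvents", "GimbalLockError",
           "grood_suntay", "joint_angle_series", "residual_cutoff",
           "butterworth_lowpass", "detect_gait_events", "normalize_to_stance",
           "STANCE_SAMPLES"]

#: Number of percent-stance samples (0-100 % at 1 % steps).
STANCE_SAMPLES = 101

#: Default filter cutoff when auto-selection is disabled, Hz.
DEFAULT_CUTOFF_HZ = 10.0

ANGLE_CHANNELS = ("dorsiflexion", "inversion", "internal_rotation")


class GimbalLockError(ValueError):
    """Raised when the body-fixed axes align and the floating axis vanishes."""


@dataclass
class GaitEvents:
    """Stance-phase bounds detected from the vertical force trace."""

    heel_strike: int
    toe_off: int
    threshold_n: float

    def __post_init__(self):
        if self.heel_strike >= self.toe_off:
            raise ValueError("heel strike must precede toe off")


@dataclass
class JointAngles:
    """Per-frame angles (deg) plus their 101-sample percent-stance curves."""

    dorsiflexion: np.ndarray
    inversion: np.ndarray
    internal_rotation: np.ndarray
    percent_stance: np.ndarray | None = None
    normalized: dict | None = None

    def as_dict(self) -> dict:
        return {"dorsiflexion": self.dorsiflexion,
                "inversion": self.inversion,
                "internal_rotation": self.internal_rotation}


def _working_basis(basis: np.ndarray) -> np.ndarray:
    """Right-handed triple: flip ML when the stored frame is left-handed."""
    if np.linalg.det(basis) < 0:
        basis = basis.copy()
        basis[:, 0] = -basis[:, 0]
    return basis


def grood_suntay(tibia_pose: Pose | None, talus_pose: Pose | None,
                 tibia_frame: AnatomicalFrame, talus_frame: AnatomicalFrame,
                 side: str | None = None) -> tuple[float, float, float]:
    """Joint-coordinate-system angles of the talus relative to the tibia.

    Returns ``(dorsiflexion, inversion, internal_rotation)`` in degrees,
    positive per clinical convention on both limbs.  ``None`` poses mean
    identity (frames already expressed in a common space).
    """
    side = side or tibia_frame.side
    A = tibia_frame.basis if tibia_pose is None else tibia_pose.rotation @ tibia_frame.basis
    B = talus_frame.basis if talus_pose is None else talus_pose.rotation @ talus_frame.basis
    Q = _working_basis(A).T @ _working_basis(B)
    if abs(Q[0, 2]) > 1.0 - 1e-9:
        raise GimbalLockError(
            "tibial ML axis parallel to talar SI axis: floating axis undefined")
    a, b, c = Rotation.from_matrix(Q).as_euler("XYZ")
    s = 1.0 if side == "right" else -1.0
    return (float(np.degrees(a)), float(-s * np.degrees(b)),
            float(-s * np.degrees(c)))


def joint_angle_series(tibia_poses, talus_poses,
                       tibia_frame: AnatomicalFrame,
                       talus_frame: AnatomicalFrame,
                       side: str | None = None) -> JointAngles:
    """Per-frame Grood-Suntay angles over a tracked sequence."""
    if len(tibia_poses) != len(talus_poses):
        raise ValueError("tibia and talus pose sequences differ in length")
    out = {k: np.empty(len(tibia_poses)) for k in ANGLE_CHANNELS}
    for i, (pt, pl) in enumerate(zip(tibia_poses, talus_poses)):
        df, inv, ir = grood_suntay(pt, pl, tibia_frame, talus_frame, side)
        out["dorsiflexion"][i] = df
        out["inversion"][i] = inv
        out["internal_rotation"][i] = ir
    return JointAngles(**out)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _design(cutoff_hz: float, fs_hz: float, order_interpretation: str):
    if cutoff_hz >= fs_hz / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    if order_interpretation == "effective":
        design_order = 2  # doubled by the bidirectional pass -> 4th order
    elif order_interpretation == "per_pass":
        design_order = 4  # effective 8th order
    else:
        raise ValueError(f"unknown order interpretation {order_interpretation!r}")
    return butter(design_order, cutoff_hz / (fs_hz / 2.0))


def butterworth_lowpass(signal: np.ndarray, fs_hz: float, cutoff_hz: float,
                        order_interpretation: str = "effective") -> np.ndarray:
    """Zero-phase (bidirectional) low-pass Butterworth filter.

    The nominal fourth order is reached by filtering a second-order design
    forward and backward; ``order_interpretation="per_pass"`` instead runs
    a fourth-order design each way.  Edges are handled by reflection
    padding of at least three filter lengths.
    """
    signal = np.asarray(signal, dtype=float)
    b, a = _design(cutoff_hz, fs_hz, order_interpretation)
    padlen = 3 * max(len(a), len(b))
    if signal.shape[-1] <= padlen:
        raise ValueError("signal too short for the filter's edge padding")
    return filtfilt(b, a, signal, padtype="even", padlen=padlen)


def residual_cutoff(signal: np.ndarray, fs_hz: float,
                    candidate_step_hz: float = 0.5,
                    order_interpretation: str = "effective") -> float:
    """Residual-analysis (Winter) selection of a low-pass cutoff.

    The RMS residual between the raw and filtered signal is evaluated on a
    0.5 Hz grid of candidate cutoffs; a line is fitted to the
    noise-dominated high-frequency tail, and the chosen cutoff is the
    lowest candidate whose residual drops to the line's zero-frequency
    intercept (the estimated noise floor).
    """
    signal = np.asarray(signal, dtype=float)
    b, a = _design(1.0, fs_hz, order_interpretation)  # for length check only
    if signal.size < 4 * 3 * max(len(a), len(b)):
        raise ValueError("signal shorter than four filter lengths")
    f_max = fs_hz / 2.0 - candidate_step_hz
    candidates = np.arange(candidate_step_hz, f_max, candidate_step_hz)
    residual = np.array([
        np.sqrt(np.mean((signal - butterworth_lowpass(
            signal, fs_hz, fc, order_interpretation)) ** 2))
        for fc in candidates])
    # linear fit to the top-quarter tail, extrapolated to 0 Hz; a small
    # relative floor keeps the rule meaningful for noiseless signals,
    # whose residual never reaches exactly zero inside the roll-off
    tail = candidates >= candidates[int(0.75 * len(candidates))]
    _slope, intercept = np.polyfit(candidates[tail], residual[tail], 1)
    floor = max(intercept, 0.0) + 0.02 * float(np.std(signal))
    below = residual <= floor
    if not below.any():
        return float(candidates[-1])
    return float(candidates[np.argmax(below)])


# ---------------------------------------------------------------------------
# Gait events and stance normalization
# ---------------------------------------------------------------------------

def detect_gait_events(force_n: np.ndarray, fs_hz: float,
                       threshold_fraction: float = 0.05,
                       debounce_s: float = 0.010) -> GaitEvents:
    """Heel strike / toe off from the vertical ground-reaction force.

    The threshold is 5 % of the trace maximum; supra-threshold runs
    shorter than the 10 ms debounce window are ignored.  Heel strike is
    the first sample of the first surviving run, toe off the last sample
    of the last one.
    """
    force = np.asarray(force_n, dtype=float)
    if force.size == 0 or force.max() <= 0:
        raise ValueError("force trace never rises above zero")
    threshold = threshold_fraction * force.max()
    above = force > threshold
    if not above.any():
        raise ValueError("force trace never crosses the 5% threshold")
    min_run = max(1, int(round(debounce_s * fs_hz)))
    edges = np.diff(np.concatenate([[0], above.astype(int), [0]]))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]  # exclusive
    runs = [(s, e) for s, e in zip(starts, ends) if e - s >= min_run]
    if not runs:
        raise ValueError("no supra-threshold run survives the debounce window")
    return GaitEvents(heel_strike=int(runs[0][0]), toe_off=int(runs[-1][1] - 1),
                      threshold_n=float(threshold))


def normalize_to_stance(series, events: GaitEvents) -> np.ndarray | dict:
    """Resample angle channels onto the 0-100 % stance grid (101 samples).

    ``series`` may be a 1-D array or a dict of 1-D arrays sampled at the
    trajectory frame rate; linear interpolation is used between frames.
    """
    if isinstance(series, dict):
        return {k: normalize_to_stance(v, events) for k, v in series.items()}
    y = np.asarray(series, dtype=float)
    hs, to = events.heel_strike, events.toe_off
    if to - hs < 1:
        raise ValueError("fewer than 2 frames within stance")
    if to >= y.size:
        raise ValueError("toe-off frame beyond the end of the series")
    grid = hs + (to - hs) * np.linspace(0.0, 1.0, STANCE_SAMPLES)
    return np.interp(grid, np.arange(y.size), y)
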