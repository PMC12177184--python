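"""Jump-event detection and kinematic estimators.

The body is treated as a rigid rod whose endpoints are the tracked head and
abdomen-tip points; its centroid proxies the centre of mass and its
orientation (the body angle, measured counter-clockwise from +x of the
abdomen-to-head vector) carries the pitch rotation.  Take-off is the first
frame at which the tarsus has permanently left the substrate; contact is
the first frame at which the head reaches the overhead target.

Velocities come in two flavours, matching how they are used downstream:

* *secant* estimates -- displacement (or unwrapped angle change) between two
  designated frames divided by the elapsed time, i.e. a whole-jump average;
* *local* estimates -- least-squares slope over a short symmetric window,
  i.e. an instantaneous value at a frame of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import DegenerateGeometryError, EventDetectionError
from .trackio import Morphometrics, TrackedTrajectory


@dataclass(frozen=True)
class JumpEvents:
    """Frame indices of the three frames of interest of one jump."""

    stationary_frame: int
    takeoff_frame: int
    contact_frame: int

    def __post_init__(self) -> None:
        if not (self.stationary_frame < self.takeoff_frame < self.contact_frame):
            raise ValueError(
                "events must satisfy stationary < takeoff < contact, got "
                f"{self.stationary_frame} / {self.takeoff_frame} / "
                f"{self.contact_frame}"
            )


@dataclass(frozen=True)
class JumpKinematics:
    """Derived per-jump kinematic quantities (SI units, FTJ angles in deg)."""

    jump_id: str
    animal_id: str
    target_height: float
    events: JumpEvents
    lv_secant: float  # m/s, take-off -> contact
    av_secant: float  # rad/s, take-off -> contact (signed)
    lv_takeoff: float  # m/s, local estimate at take-off
    av_takeoff: float  # rad/s, local estimate at take-off
    body_angle_takeoff: float  # rad
    ftj_rest: float  # deg, at the stationary frame
    ftj_takeoff: float  # deg, at the take-off frame
    air_time: float  # s
    total_rotation: float  # rad, unwrapped take-off -> contact


# ---------------------------------------------------------------------------
# event detection


def detect_takeoff(
    traj: TrackedTrajectory,
    substrate_y: float = 0.0,
    clearance: float = 5e-4,
) -> int:
    """First frame at which the tarsus clears the substrate for good.

    The tarsus must exceed ``substrate_y + clearance`` at the returned frame
    and at every later frame of the trajectory (which ends at target
    contact), so transient tracking-noise spikes during stance do not
    trigger a false take-off.
    """
    if not clearance > 0:
        raise ValueError("clearance must be > 0")
    y = traj.point("tarsus")[:, 1]
    above = y > substrate_y + clearance
    if not above.any():
        raise EventDetectionError(f"{traj.jump_id}: no take-off detected")
    # first index from which `above` holds to the end
    below_idx = np.nonzero(~above)[0]
    if below_idx.size == 0:
        raise EventDetectionError(
            f"{traj.jump_id}: tarsus airborne from the first frame"
        )
    takeoff = int(below_idx[-1] + 1)
    if takeoff >= traj.n_frames:
        raise EventDetectionError(f"{traj.jump_id}: no take-off detected")
    return takeoff


def detect_contact(
    traj: TrackedTrajectory,
    target_y: float | None = None,
    tolerance: float = 1e-3,
) -> int:
    """First frame at which the head reaches the overhead target.

    The head approaches the target from below, so the criterion is one-sided:
    the first frame with head y >= ``target_y - tolerance``.
    """
    if not tolerance > 0:
        raise ValueError("tolerance must be > 0")
    if target_y is None:
        target_y = traj.target_height
    y = traj.point("head")[:, 1]
    hit = np.nonzero(y >= target_y - tolerance)[0]
    if hit.size == 0:
        raise EventDetectionError(f"{traj.jump_id}: no contact detected")
    return int(hit[0])


def detect_stationary(
    traj: TrackedTrajectory, motion_threshold: float = 3e-4
) -> int:
    """Last frame before the body centroid has moved off its initial position.

    Returns the frame preceding the first centroid displacement from frame 0
    exceeding ``motion_threshold`` (m).  With the default threshold a few
    times the tracking-noise scale, this lands in the resting phase.
    """
    c = centroid_series(traj)
    disp = np.linalg.norm(c - c[0], axis=1)
    moving = np.nonzero(disp > motion_threshold)[0]
    if moving.size == 0:
        raise EventDetectionError(f"{traj.jump_id}: no movement detected")
    return max(int(moving[0]) - 1, 0)


# ---------------------------------------------------------------------------
# geometry


def centroid_series(traj: TrackedTrajectory) -> np.ndarray:
    """(n, 2) midpoint of head and abdomen tip -- centre-of-mass proxy."""
    return 0.5 * (traj.point("head") + traj.point("abdomen"))


def body_centroid(traj: TrackedTrajectory, frame: int) -> np.ndarray:
    traj._check_frame(frame)
    return centroid_series(traj)[frame]


def body_angle_series(traj: TrackedTrajectory) -> np.ndarray:
    """Unwrapped body angle per frame: abdomen->head vector vs +x, rad.

    Unwrapping removes the 2-pi jumps of atan2 so consecutive differences
    always lie in (-pi, pi); positive rotation carries the head over the
    animal's back (counter-clockwise when the animal faces +x).
    """
    d = traj.point("head") - traj.point("abdomen")
    if np.any(np.all(d == 0.0, axis=1)):
        bad = int(np.nonzero(np.all(d == 0.0, axis=1))[0][0])
        raise DegenerateGeometryError(
            f"{traj.jump_id}: degenerate body axis at frame {bad}"
        )
    return np.unwrap(np.arctan2(d[:, 1], d[:, 0]))


def body_angle(traj: TrackedTrajectory, frame: int) -> float:
    traj._check_frame(frame)
    d = traj.coords("head", frame) - traj.coords("abdomen", frame)
    if d[0] == 0.0 and d[1] == 0.0:
        raise DegenerateGeometryError(
            f"{traj.jump_id}: degenerate body axis at frame {frame}"
        )
    return float(np.arctan2(d[1], d[0]))


def ftj_angle(traj: TrackedTrajectory, frame: int) -> float:
    """Interior angle at the femorotibial joint, degrees in [0, 180].

    Measured at the ftj vertex between the rays toward the proximal landmark
    (the abdomen tip, standing in for the femur's body end) and toward the
    tarsus.  Invariant under global rotation and translation.
    """
    traj._check_frame(frame)
    a = traj.coords("abdomen", frame)
    v = traj.coords("ftj", frame)
    t = traj.coords("tarsus", frame)
    u1 = a - v
    u2 = t - v
    n1 = np.linalg.norm(u1)
    n2 = np.linalg.norm(u2)
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateGeometryError(
            f"{traj.jump_id}: degenerate joint at frame {frame}"
        )
    cosang = np.clip(np.dot(u1, u2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# velocity estimators


def secant_linear_velocity(traj: TrackedTrajectory, f1: int, f2: int) -> float:
    """Centroid displacement between two frames over the elapsed time, m/s.

    The elapsed time is (f2 - f1) / frame_rate; this is the whole-interval
    average speed, not an instantaneous value.
    """
    if not f1 < f2:
        raise ValueError(f"need f1 < f2, got {f1} >= {f2}")
    traj._check_frame(f1)
    traj._check_frame(f2)
    c = centroid_series(traj)
    dt = (traj.frames[f2] - traj.frames[f1]) / traj.frame_rate
    return float(np.linalg.norm(c[f2] - c[f1]) / dt)


def secant_angular_velocity(traj: TrackedTrajectory, f1: int, f2: int) -> float:
    """Unwrapped body-angle change between two frames over elapsed time, rad/s."""
    if not f1 < f2:
        raise ValueError(f"need f1 < f2, got {f1} >= {f2}")
    traj._check_frame(f1)
    traj._check_frame(f2)
    theta = body_angle_series(traj)
    dt = (traj.frames[f2] - traj.frames[f1]) / traj.frame_rate
    return float((theta[f2] - theta[f1]) / dt)


def local_velocity(
    traj: TrackedTrajectory, frame: int, window: int = 5
) -> tuple[float, float]:
    """Instantaneous (lv, av) at a frame: least-squares slope over a window.

    The window is symmetric, ``window`` frames wide (>= 2), and must lie
    inside the trajectory.  For window == 2 this reduces to a forward/central
    finite difference.
    """
    if window < 2:
        raise ValueError("window must span at least 2 frames")
    half_lo = (window - 1) // 2
    half_hi = window // 2
    lo, hi = frame - half_lo, frame + half_hi
    if lo < 0 or hi >= traj.n_frames:
        raise ValueError(
            f"{traj.jump_id}: window [{lo}, {hi}] extends past trajectory"
        )
    sl = slice(lo, hi + 1)
    t = traj.times[sl]
    c = centroid_series(traj)[sl]
    theta = body_angle_series(traj)[sl]
    A = np.vstack([t - t.mean(), np.ones_like(t)]).T
    vx, _ = np.linalg.lstsq(A, c[:, 0], rcond=None)[0]
    vy, _ = np.linalg.lstsq(A, c[:, 1], rcond=None)[0]
    om, _ = np.linalg.lstsq(A, theta, rcond=None)[0]
    return float(np.hypot(vx, vy)), float(om)


def total_rotation(traj: TrackedTrajectory, events: JumpEvents) -> float:
    """Unwrapped body-angle change from take-off to contact, rad (signed)."""
    traj._check_frame(events.takeoff_frame)
    traj._check_frame(events.contact_frame)
    theta = body_angle_series(traj)
    return float(theta[events.contact_frame] - theta[events.takeoff_frame])


# ---------------------------------------------------------------------------
# full per-jump analysis


def analyze_jump(
    traj: TrackedTrajectory,
    morph: Morphometrics | None = None,
    substrate_y: float = 0.0,
    target_y: float | None = None,
    *,
    clearance: float = 5e-4,
    tolerance: float = 1e-3,
    window: int = 5,
    motion_threshold: float = 3e-4,
) -> JumpKinematics:
    """Detect the jump events and compute every kinematic estimate.

    Secant velocities span take-off to contact (the whole-jump averages);
    local velocities are evaluated just after take-off on a flight-only
    window, so the stance phase does not leak into the instantaneous
    estimate.  FTJ angles are read at the stationary and take-off frames.
    """
    try:
        takeoff = detect_takeoff(traj, substrate_y, clearance)
        contact = detect_contact(traj, target_y, tolerance)
        stationary = detect_stationary(traj, motion_threshold)
    except EventDetectionError:
        raise
    if contact <= takeoff:
        raise EventDetectionError(
            f"{traj.jump_id}: contact frame {contact} not after take-off "
            f"{takeoff}"
        )
    if stationary >= takeoff:
        stationary = max(takeoff - 1, 0)
    events = JumpEvents(stationary, takeoff, contact)

    lv_sec = secant_linear_velocity(traj, takeoff, contact)
    av_sec = secant_angular_velocity(traj, takeoff, contact)

    # local estimate on flight frames only: centre the window just past
    # take-off; shrink it for very short flights
    w = min(window, contact - takeoff + 1)
    w = max(w, 2)
    center = min(takeoff + (w - 1) // 2, contact - w // 2)
    lv_to, av_to = local_velocity(traj, center, w)

    air_time = (traj.frames[contact] - traj.frames[takeoff]) / traj.frame_rate
    return JumpKinematics(
        jump_id=traj.jump_id,
        animal_id=traj.animal_id,
        target_height=traj.target_height,
        events=events,
        lv_secant=lv_sec,
        av_secant=av_sec,
        lv_takeoff=lv_to,
        av_takeoff=av_to,
        body_angle_takeoff=body_angle(traj, takeoff),
        ftj_rest=ftj_angle(traj, stationary),
        ftj_takeoff=ftj_angle(traj, takeoff),
        air_time=float(air_time),
        total_rotation=total_rotation(traj, events),
    )
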