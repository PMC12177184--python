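"""Ballistic free flight with constant body rotation.

After take-off the only force on the body is gravity, so the centre of mass
follows the closed-form projectile parabola while the body spins at the
constant pitch rate it left the ground with (no aerodynamic torque).  An
inverted overhead landing requires the body to rotate through pi radians
(180 degrees) between take-off and target contact; given the ballistic
flight time T to the target, the required spin is simply pi / T.

All trajectory values are evaluated from the closed form -- the sampler
discretizes time, never integrates -- so sampled paths agree with the
analytic solution to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._errors import UnreachableTargetError

G_DEFAULT = 9.81  # m s^-2
INVERSION_ROTATION = math.pi  # rad, rotation for an inverted landing
SUCCESS_TOLERANCE = 0.35  # rad (~20 deg) around pi that still counts as landed


@dataclass(frozen=True)
class TakeoffState:
    """Initial conditions of the ballistic phase."""

    speed: float  # m/s
    elevation_angle: float = math.pi / 2  # rad from horizontal
    initial_height: float = 0.0  # m, y0 of the centre of mass
    initial_body_angle: float = 0.0  # rad
    angular_velocity: float = 0.0  # rad/s, constant in flight

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if not (0.0 < self.elevation_angle <= math.pi / 2):
            raise ValueError("elevation_angle must be in (0, pi/2]")
        if self.initial_height < 0:
            raise ValueError("initial_height must be >= 0")


@dataclass(frozen=True)
class FlightResult:
    air_time: float  # s
    contact_x: float  # m, horizontal position at contact
    rotation_at_contact: float  # rad, angular_velocity * air_time
    success: bool  # rotation within tolerance of an inverted landing
    sampled_path: np.ndarray = field(repr=False)  # (n, 4): t, x, y, theta


def time_to_height(
    speed: float,
    elevation_angle: float,
    y0: float,
    target_height: float,
    g: float = G_DEFAULT,
) -> float:
    """Time for the ascending ballistic path to first reach a target height.

    Smallest non-negative root of y0 + v_y t - g t^2 / 2 = target_height.
    Raises :class:`UnreachableTargetError` when the vertical speed cannot
    carry the body that high (v_y^2 < 2 g (target - y0)).
    """
    if not g > 0:
        raise ValueError("g must be > 0")
    vy = speed * math.sin(elevation_angle)
    if target_height <= y0:
        return 0.0
    if not vy > 0:
        raise UnreachableTargetError("insufficient take-off speed")
    disc = vy**2 - 2.0 * g * (target_height - y0)
    if disc < 0:
        raise UnreachableTargetError(
            f"insufficient take-off speed: v_y = {vy:.3f} m/s cannot reach "
            f"{target_height - y0:.4f} m above take-off"
        )
    return (vy - math.sqrt(disc)) / g


def required_av(air_time: float, rotation_needed: float = INVERSION_ROTATION) -> float:
    """Constant spin achieving ``rotation_needed`` over ``air_time``, rad/s."""
    if not air_time > 0:
        raise ValueError("air_time must be > 0")
    return rotation_needed / air_time


def _wrap(angle: float) -> float:
    """Wrap to (-pi, pi]."""
    return float(-((-angle + math.pi) % (2.0 * math.pi) - math.pi))


def simulate_flight(
    state: TakeoffState,
    target_height: float,
    g: float = G_DEFAULT,
    dt: float = 1.0 / 2000.0,
    success_tolerance: float = SUCCESS_TOLERANCE,
) -> FlightResult:
    """Fly the closed-form path to the target, sampling at ``dt``.

    Success means the body angle at contact sits within
    ``success_tolerance`` of a half-turn from take-off (in either spin
    direction): the animal arrives inverted and can grip the underside of
    the target.  The default sampling step mirrors a 2000 Hz camera.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    air_time = time_to_height(
        state.speed, state.elevation_angle, state.initial_height, target_height, g
    )
    vy = state.speed * math.sin(state.elevation_angle)
    vx = state.speed * math.cos(state.elevation_angle)
    t = np.arange(0.0, air_time, dt)
    if t.size == 0 or t[-1] < air_time:
        t = np.append(t, air_time)
    x = vx * t
    y = state.initial_height + vy * t - 0.5 * g * t**2
    theta = state.initial_body_angle + state.angular_velocity * t
    path = np.column_stack([t, x, y, theta])
    rotation = state.angular_velocity * air_time
    success = abs(_wrap(rotation - INVERSION_ROTATION)) <= success_tolerance
    return FlightResult(
        air_time=float(air_time),
        contact_x=float(x[-1]),
        rotation_at_contact=float(rotation),
        success=bool(success),
        sampled_path=path,
    )


def feasibility_map(
    target_height: float,
    speed_grid: np.ndarray,
    av_grid: np.ndarray,
    elevation_angle: float = math.pi / 2,
    y0: float = 0.0,
    g: float = G_DEFAULT,
    success_tolerance: float = SUCCESS_TOLERANCE,
) -> np.ndarray:
    """Boolean grid: which (speed, spin) pairs land inverted on the target.

    Entry [i, j] is True when speed_grid[i] reaches the target and
    av_grid[j] * flight_time is within tolerance of a half turn.  Speeds
    that cannot reach the target are infeasible, not errors.
    """
    speeds = np.asarray(speed_grid, dtype=float)
    avs = np.asarray(av_grid, dtype=float)
    if speeds.size == 0 or avs.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(speeds < 0) or np.any(avs < 0):
        raise ValueError("grids must be non-negative")
    out = np.zeros((speeds.size, avs.size), dtype=bool)
    for i, v in enumerate(speeds):
        try:
            t_hit = time_to_height(v, elevation_angle, y0, target_height, g)
        except UnreachableTargetError:
            continue
        if t_hit <= 0:
            continue
        rot = avs * t_hit
        wrapped = np.abs((rot - INVERSION_ROTATION + math.pi) % (2 * math.pi) - math.pi)
        out[i, :] = wrapped <= success_tolerance
    return out
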