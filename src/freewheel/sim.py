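"""Closed-loop wheelchair simulator.

The chair consumes the same two 0-5 V analog channels the joystick would
produce: one channel drives linear speed, the other angular speed, both
linear and odd about the 2.5 V rest point.  Pose integrates under unicycle
kinematics, and an ultrasonic anti-collision gate inhibits forward motion
whenever an obstacle's boundary lies within 1.2 m inside the forward sensing
cone — turning and reversing stay available so the user can always maneuver
away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .head import ControlVoltages

#: anti-collision sensing range, meters
ULTRASONIC_RANGE_M = 1.2

#: half-angle of the forward sensing cone, radians
FORWARD_CONE_HALF_ANGLE = math.pi / 6


@dataclass(frozen=True)
class WheelchairState:
    x: float = 0.0
    y: float = 0.0
    heading: float = 0.0  # radians, normalized to (-pi, pi]
    v: float = 0.0
    omega: float = 0.0
    t: float = 0.0


@dataclass(frozen=True)
class DriveParams:
    """Voltage-to-velocity scaling and integration step.

    ``swap_axes`` exchanges which voltage channel drives speed vs turn.
    """

    v_max: float = 1.0
    omega_max: float = math.pi / 2
    v_ref: float = 2.5
    volts_span: float = 2.5
    dt: float = 0.05
    swap_axes: bool = False

    def __post_init__(self) -> None:
        for name in ("v_max", "omega_max", "v_ref", "volts_span", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Obstacle:
    x: float
    y: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("obstacle radius must be positive")


def _wrap_angle(a: float) -> float:
    """Normalize to (-pi, pi]."""
    a = (a + math.pi) % (2 * math.pi) - math.pi
    return math.pi if a == -math.pi else a


def voltages_to_velocities(
    volts: ControlVoltages, params: DriveParams = DriveParams()
) -> tuple[float, float]:
    """Linear map from the two control voltages to (v, omega)."""
    for v in (volts.vx, volts.vy):
        if not 0.0 <= v <= 5.0:
            raise ValueError(f"control voltage {v} outside [0, 5] V")
    speed_volts, turn_volts = (volts.vy, volts.vx) if params.swap_axes else (volts.vx, volts.vy)
    v = params.v_max * (speed_volts - params.v_ref) / params.volts_span
    omega = params.omega_max * (turn_volts - params.v_ref) / params.volts_span
    return v, omega


def step_kinematics(
    state: WheelchairState, v: float, omega: float, params: DriveParams = DriveParams()
) -> WheelchairState:
    """One unicycle integration step: turn first, then advance along heading."""
    heading = _wrap_angle(state.heading + omega * params.dt)
    return WheelchairState(
        x=state.x + v * math.cos(heading) * params.dt,
        y=state.y + v * math.sin(heading) * params.dt,
        heading=heading,
        v=v,
        omega=omega,
        t=state.t + params.dt,
    )


def ultrasonic_gate(
    state: WheelchairState,
    obstacles: list[Obstacle],
    v: float,
    omega: float,
    range_m: float = ULTRASONIC_RANGE_M,
    cone_half_angle: float = FORWARD_CONE_HALF_ANGLE,
) -> tuple[float, float]:
    """Inhibit forward motion when an obstacle boundary is inside the cone.

    Only forward velocity is gated; turning in place and reversing pass
    through unchanged (the sensors face front only).
    """
    if range_m <= 0:
        raise ValueError("sensing range must be positive")
    if v <= 0:
        return v, omega
    for ob in obstacles:
        dx, dy = ob.x - state.x, ob.y - state.y
        dist = math.hypot(dx, dy)
        boundary = dist - ob.radius
        if boundary > range_m:
            continue
        bearing = _wrap_angle(math.atan2(dy, dx) - state.heading)
        if abs(bearing) <= cone_half_angle:
            return 0.0, omega
    return v, omega


def run_closed_loop(
    voltages,
    obstacles: list[Obstacle] | None = None,
    params: DriveParams = DriveParams(),
    start: WheelchairState = WheelchairState(),
    range_m: float = ULTRASONIC_RANGE_M,
) -> pd.DataFrame:
    """Drive the simulated chair through a stream of control voltages.

    ``voltages`` is an iterable of :class:`ControlVoltages` (or (vx, vy)
    pairs), one per time step.  Returns a `t,x,y,heading,v,omega` trace with
    one row per step plus the initial state; deterministic for deterministic
    inputs.
    """
    obstacles = obstacles or []
    state = start
    rows = [state]
    for item in voltages:
        volts = item if isinstance(item, ControlVoltages) else ControlVoltages(*item)
        v, omega = voltages_to_velocities(volts, params)
        v, omega = ultrasonic_gate(state, obstacles, v, omega, range_m=range_m)
        state = step_kinematics(state, v, omega, params)
        rows.append(state)
    return pd.DataFrame(
        {
            "t": [s.t for s in rows],
            "x": [s.x for s in rows],
            "y": [s.y for s in rows],
            "heading": [s.heading for s in rows],
            "v": [s.v for s in rows],
            "omega": [s.omega for s in rows],
        }
    )
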