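"""Head-tilt interface: gravity-projection inclination angles and the cubic
dead-zone mapping from angles to joystick-replacement voltages.

A head-worn 3-axis accelerometer at rest measures only gravity, so the head's
pitch (theta_x, forward/backward) and roll (theta_y, left/right) follow from
the projection of the gravity vector onto the sensor axes:

    theta_x = atan( ax / sqrt(ay^2 + az^2) )
    theta_y = atan( ay / sqrt(ax^2 + az^2) )

both in [-90, +90] degrees.  A cubic curve with a flat centre then maps each
angle to a control voltage around the 2.5 V rest point, so small involuntary
head movements stay inside a dead zone while deliberate tilts ramp the
voltage smoothly toward the 0/5 V rails.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .commands import Direction


class DegenerateInputError(ValueError):
    """Raised when an acceleration vector carries no orientation information."""


@dataclass(frozen=True)
class AccelSample:
    """One 3-axis accelerometer reading in units of g."""

    ax: float
    ay: float
    az: float
    t: float = 0.0


@dataclass(frozen=True)
class TiltAngles:
    """Head inclination pair in degrees, each in [-90, +90]."""

    theta_x: float
    theta_y: float

    def __post_init__(self) -> None:
        for v in (self.theta_x, self.theta_y):
            if not -90.0 <= v <= 90.0:
                raise ValueError(f"inclination angle {v} outside [-90, 90]")


@dataclass(frozen=True)
class CubicMapParams:
    """Parameters of the cubic angle-to-voltage map.

    ``v = clamp(m * (theta - r)^3 / s + v_ref)`` per axis; ``m``/``n`` are the
    slope factors for the x/y axes, ``r`` shifts the quasi-linear zone along
    the angle axis (degrees) and ``s`` (degrees^3) scales it: larger ``s``
    flattens the curve.  Defaults saturate the output at a 30 degree tilt,
    a comfortable head excursion, and are all adjustable per user.
    ``invert_x``/``invert_y`` flip the sign of the centred angle for users who
    prefer the opposite tilt convention.
    """

    m: float = 2.5
    n: float = 2.5
    r: float = 0.0
    s: float = 27000.0
    v_ref: float = 2.5
    v_min: float = 0.0
    v_max: float = 5.0
    dead_zone_deg: float = 10.0
    invert_x: bool = False
    invert_y: bool = False

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("scale factor s must be positive")
        if not self.v_min < self.v_ref < self.v_max:
            raise ValueError("require v_min < v_ref < v_max")
        if self.dead_zone_deg < 0:
            raise ValueError("dead_zone_deg must be nonnegative")


@dataclass(frozen=True)
class ControlVoltages:
    """The two analog control outputs, clamped to the joystick's 0-5 V span."""

    vx: float
    vy: float


class HeadAction(str, enum.Enum):
    FORWARD = "forward"
    BACKWARD = "backward"
    LEFT = "left"
    RIGHT = "right"
    NEUTRAL = "neutral"


_HEAD_TO_DIRECTION = {
    HeadAction.FORWARD: Direction.FORWARD,
    HeadAction.BACKWARD: Direction.BACKWARD,
    HeadAction.LEFT: Direction.LEFT,
    HeadAction.RIGHT: Direction.RIGHT,
}


def tilt_from_accel(sample: AccelSample) -> TiltAngles:
    """Recover head inclination angles from a static acceleration reading.

    Scale-invariant: only the direction of the acceleration vector matters.
    A zero denominator yields +/-90 degrees by the sign of the numerator; an
    all-zero vector is a :class:`DegenerateInputError`.
    """
    ax, ay, az = float(sample.ax), float(sample.ay), float(sample.az)
    if ax == 0.0 and ay == 0.0 and az == 0.0:
        raise DegenerateInputError("all-zero acceleration vector has no tilt")
    den_x = math.hypot(ay, az)
    den_y = math.hypot(ax, az)
    theta_x = math.degrees(math.atan(ax / den_x)) if den_x > 0 else math.copysign(90.0, ax)
    theta_y = math.degrees(math.atan(ay / den_y)) if den_y > 0 else math.copysign(90.0, ay)
    return TiltAngles(theta_x, theta_y)


def _centered(angles: TiltAngles, params: CubicMapParams) -> tuple[float, float]:
    cx = angles.theta_x - params.r
    cy = angles.theta_y - params.r
    if params.invert_x:
        cx = -cx
    if params.invert_y:
        cy = -cy
    return cx, cy


def cubic_map(angles: TiltAngles, params: CubicMapParams = CubicMapParams()) -> ControlVoltages:
    """Map inclination angles to control voltages through the cubic dead zone."""
    cx, cy = _centered(angles, params)
    vx = params.m * cx**3 / params.s + params.v_ref
    vy = params.n * cy**3 / params.s + params.v_ref
    clamp = lambda v: min(max(v, params.v_min), params.v_max)
    return ControlVoltages(clamp(vx), clamp(vy))


def classify_head_direction(
    angles: TiltAngles, params: CubicMapParams = CubicMapParams()
) -> HeadAction:
    """Classify a tilt into a discrete head action.

    Neutral while both centred angles sit inside the dead zone; otherwise the
    dominant axis (larger absolute centred angle, ties to the x axis) picks
    the action: up-tilt drives forward, down backward, right/left turn.
    """
    cx, cy = _centered(angles, params)
    if abs(cx) <= params.dead_zone_deg and abs(cy) <= params.dead_zone_deg:
        return HeadAction.NEUTRAL
    if abs(cx) >= abs(cy):
        return HeadAction.FORWARD if cx > 0 else HeadAction.BACKWARD
    return HeadAction.RIGHT if cy > 0 else HeadAction.LEFT


def head_action_direction(action: HeadAction) -> Direction | None:
    """The drive direction for a head action, or None for neutral."""
    return _HEAD_TO_DIRECTION.get(action)


# ---------------------------------------------------------------------------
# trace-level helpers (CSV dialect: header t,ax,ay,az in seconds and g)

def read_accel_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["t", "ax", "ay", "az"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"accel CSV missing columns: {missing}")
    return df[required]


def tilt_trace(accel: pd.DataFrame) -> pd.DataFrame:
    """Vectorized tilt estimation over a `t,ax,ay,az` frame -> `t,theta_x,theta_y`."""
    ax = accel["ax"].to_numpy(float)
    ay = accel["ay"].to_numpy(float)
    az = accel["az"].to_numpy(float)
    if np.any((ax == 0) & (ay == 0) & (az == 0)):
        raise DegenerateInputError("trace contains an all-zero acceleration sample")
    with np.errstate(divide="ignore"):
        tx = np.degrees(np.arctan2(ax, np.hypot(ay, az)))
        ty = np.degrees(np.arctan2(ay, np.hypot(ax, az)))
    return pd.DataFrame({"t": accel["t"], "theta_x": tx, "theta_y": ty})


def voltage_trace(accel: pd.DataFrame, params: CubicMapParams = CubicMapParams()) -> pd.DataFrame:
    """Full head pipeline over a trace: accelerations -> angles -> `t,vx,vy`."""
    ang = tilt_trace(accel)
    cx = ang["theta_x"].to_numpy() - params.r
    cy = ang["theta_y"].to_numpy() - params.r
    if params.invert_x:
        cx = -cx
    if params.invert_y:
        cy = -cy
    vx = np.clip(params.m * cx**3 / params.s + params.v_ref, params.v_min, params.v_max)
    vy = np.clip(params.n * cy**3 / params.s + params.v_ref, params.v_min, params.v_max)
    return pd.DataFrame({"t": ang["t"], "vx": vx, "vy": vy})
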