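"""Shared motion-command vocabulary used by all three input interfaces."""

from __future__ import annotations

import enum
from dataclasses import dataclass


class Direction(str, enum.Enum):
    """Semantic motion direction of the wheelchair."""

    FORWARD = "forward"
    BACKWARD = "backward"
    LEFT = "left"
    RIGHT = "right"


class Mode(str, enum.Enum):
    TIMED = "timed"
    CONTINUOUS = "continuous"


@dataclass(frozen=True)
class DriveCommand:
    """A semantic motion request: a direction plus a duration mode.

    Timed commands carry a duration of 1 or 2 seconds; continuous commands
    run until superseded by another command or a stop.
    """

    direction: Direction
    mode: Mode = Mode.CONTINUOUS
    duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.mode is Mode.TIMED:
            if self.duration_s not in (1, 2, 1.0, 2.0):
                raise ValueError("timed commands last 1 or 2 seconds")
        elif self.duration_s is not None:
            raise ValueError("continuous commands carry no duration")


@dataclass(frozen=True)
class StopCommand:
    """An explicit halt: clears any pending or active motion."""


STOP = StopCommand()
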