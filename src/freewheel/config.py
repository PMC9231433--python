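"""Platform configuration: one YAML/JSON file drives a whole session.

Exactly one interface (head, voice or eye) is selected per run, mirroring
the physical platform's one-module-at-a-time diadem.  A single master seed
fans out deterministically to per-module sub-seeds so one number reproduces
an entire session.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .filters import DcBlockerParams, EmaParams
from .head import CubicMapParams
from .sim import DriveParams
from .synth import GestureTemplateParams


class ConfigError(ValueError):
    """Raised for unreadable, unknown-key or invalid configuration input."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class HeadConfig(_Block):
    m: float = 2.5
    n: float = 2.5
    r: float = 0.0
    s: float = 27000.0
    v_ref: float = 2.5
    dead_zone_deg: float = 10.0
    invert_x: bool = False
    invert_y: bool = False

    def to_params(self) -> CubicMapParams:
        return CubicMapParams(**self.model_dump())


class EyeConfig(_Block):
    w: float = 0.2
    alpha: float = 0.95
    timeout_windows: int = 3
    holdout_fraction: float = 0.2

    def ema_params(self) -> EmaParams:
        return EmaParams(w=self.w)

    def dcb_params(self) -> DcBlockerParams:
        return DcBlockerParams(alpha=self.alpha)


class VoiceConfig(_Block):
    drop_prob: float = 0.0
    confusion_prob: float = 0.0


class DriveConfig(_Block):
    v_max: float = 1.0
    omega_max: float = float(np.pi / 2)
    dt: float = 0.05
    swap_axes: bool = False

    def to_params(self) -> DriveParams:
        return DriveParams(**self.model_dump())


class TemplateConfig(_Block):
    pulse_amp: float = 0.8
    pulse_center: int = 37
    pulse_width: int = 15
    baseline_dc: float = 2.0
    drift_slope: float = 0.001
    noise_sigma: float = 0.05
    flip_channels: bool = False

    def to_params(self, seed: int = 0) -> GestureTemplateParams:
        return GestureTemplateParams(seed=seed, **self.model_dump())


class PlatformConfig(_Block):
    """Validated top-level configuration with defaults for every block."""

    interface: Literal["head", "voice", "eye"] = "head"
    master_seed: int = 0
    head: HeadConfig = HeadConfig()
    eye: EyeConfig = EyeConfig()
    voice: VoiceConfig = VoiceConfig()
    drive: DriveConfig = DriveConfig()
    templates: TemplateConfig = TemplateConfig()

    @model_validator(mode="before")
    @classmethod
    def _single_interface(cls, data):
        if isinstance(data, dict) and isinstance(data.get("interface"), (list, tuple, set)):
            raise ValueError("exactly one interface must be selected per run")
        return data


#: named seed streams, in fan-out order
SEED_STREAMS = ("accel", "gesture", "voice", "train", "course")


def derive_seed(master_seed: int, stream: str) -> int:
    """Deterministic per-module sub-seed from the master seed.

    Spawns one child seed sequence per named stream off the master and takes
    its first 31-bit word, so streams are statistically independent and the
    derivation is documented and stable.
    """
    if stream not in SEED_STREAMS:
        raise ConfigError(f"unknown seed stream {stream!r}")
    children = np.random.SeedSequence(master_seed).spawn(len(SEED_STREAMS))
    child = children[SEED_STREAMS.index(stream)]
    return int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def load_config(path: str | Path | None = None) -> PlatformConfig:
    """Load and validate a YAML (or JSON) config; missing file section -> defaults.

    Unknown keys are rejected with the offending key path in the message.
    """
    if path is None:
        return PlatformConfig()
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ConfigError(f"unparseable config {path}: {e}") from e
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        return PlatformConfig(**data)
    except ValidationError as e:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in e.errors()
        )
        raise ConfigError(f"invalid config {path}: {locs}") from e


def dump_config(config: PlatformConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.model_dump(), indent=2))
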