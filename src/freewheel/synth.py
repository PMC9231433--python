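"""Seeded synthetic inputs for every interface.

Nothing here touches hardware: the generators emulate what the sensors would
deliver so the whole decoding pipeline can be exercised end to end.

* **IMU traces** — a static-gravity model: during a held head pose the
  accelerometer reads the unit gravity vector that the tilt equations invert
  back to the scripted angles, plus white Gaussian noise per axis.  Linear
  acceleration is deliberately absent, matching the static-pose assumption
  the tilt formulas rest on.
* **IR gesture windows** — each gesture is a template over the two channels:
  a DC baseline plus slow drift, a smooth pulse whose per-channel polarity
  distinguishes the gestures (left/right antisymmetric across channels,
  close deflects both, open stays at baseline), plus Gaussian noise.  The
  pulse is a flat-top "saccade-hold-return" deflection with smooth cosine
  shoulders, the shape a gaze hold traces on a reflectance channel.
* **voice token streams** — scripted words at scripted times, with an
  injectable per-token drop and confusion probability standing in for
  recognizer failures.

Every generator is a pure function of its inputs and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gestures import GESTURES, GestureWindow, VocabularyError, WINDOW_LEN
from .voice import VOCABULARY, VoiceToken


@dataclass(frozen=True)
class HeadMotionScript:
    """Ordered (duration_s, target_theta_x, target_theta_y) pose segments."""

    segments: tuple[tuple[float, float, float], ...]
    noise_sigma: float = 0.0
    fs: float = 50.0
    seed: int = 0
    ramp_s: float = 0.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(tuple(s) for s in self.segments))
        for dur, tx, ty in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")
            if not (-90 <= tx <= 90 and -90 <= ty <= 90):
                raise ValueError("target angles must lie in [-90, 90] degrees")


def _angles_to_gravity(tx_deg: float, ty_deg: float) -> tuple[float, float, float]:
    """Unit gravity vector whose tilt estimate equals the given angles."""
    ax = math.sin(math.radians(tx_deg))
    ay = math.sin(math.radians(ty_deg))
    rest = 1.0 - ax * ax - ay * ay
    if rest < 0:
        raise ValueError(
            f"pose ({tx_deg}, {ty_deg}) is unreachable for a static gravity vector"
        )
    return ax, ay, math.sqrt(rest)


def gen_accel_trace(script: HeadMotionScript) -> pd.DataFrame:
    """Generate a `t,ax,ay,az` trace (seconds, g) for a scripted head motion.

    Poses ramp linearly (in angle) over ``ramp_s`` at each segment boundary;
    the first segment starts on target.
    """
    rng = np.random.default_rng(script.seed)
    dt = 1.0 / script.fs
    rows_t: list[float] = []
    angles: list[tuple[float, float]] = []
    t = 0.0
    prev = None
    for dur, tx, ty in script.segments:
        n = max(1, int(round(dur * script.fs)))
        for i in range(n):
            if prev is not None and i * dt < script.ramp_s:
                frac = (i * dt) / script.ramp_s
                cx = prev[0] + frac * (tx - prev[0])
                cy = prev[1] + frac * (ty - prev[1])
            else:
                cx, cy = tx, ty
            rows_t.append(t)
            angles.append((cx, cy))
            t += dt
        prev = (tx, ty)
    g = np.array([_angles_to_gravity(cx, cy) for cx, cy in angles])
    if script.noise_sigma > 0:
        g = g + rng.normal(0.0, script.noise_sigma, size=g.shape)
    return pd.DataFrame({"t": rows_t, "ax": g[:, 0], "ay": g[:, 1], "az": g[:, 2]})


@dataclass(frozen=True)
class GestureTemplateParams:
    """Waveform template for the four IR-oculography gesture classes.

    ``pulse_amp`` sets the deflection magnitude; which channel deflects
    positively for a leftward gaze is an arbitrary convention, flipped by
    ``flip_channels``.  ``pulse_width`` is the full width of the pulse's flat
    top in samples; 4-sample cosine shoulders flank it.
    """

    pulse_amp: float = 0.8
    pulse_center: int = 37
    pulse_width: int = 15
    baseline_dc: float = 2.0
    drift_slope: float = 0.001
    noise_sigma: float = 0.05
    fs: float = 50.0
    window_len: int = WINDOW_LEN
    seed: int = 0
    flip_channels: bool = False

    def __post_init__(self) -> None:
        if self.window_len != round(self.fs * 1.5):
            raise ValueError("window_len must equal round(fs * 1.5)")

    def amplitudes(self, label: str) -> tuple[float, float]:
        """(left-channel, right-channel) pulse amplitudes for a gesture."""
        a = self.pulse_amp
        table = {
            "open": (0.0, 0.0),
            "close": (a, a),
            "left": (a, -a),
            "right": (-a, a),
        }
        if label not in table:
            raise VocabularyError(f"unknown gesture label {label!r}")
        al, ar = table[label]
        return (ar, al) if self.flip_channels else (al, ar)


def _gesture_channels(
    label: str, params: GestureTemplateParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = params.window_len
    idx = np.arange(n)
    # plateau pulse: the eye saccades to the target, holds for pulse_width
    # samples, then returns; cosine shoulders model the saccade transitions
    half = params.pulse_width / 2.0
    ramp = 4.0
    d = np.abs(idx - params.pulse_center)
    shoulder = 0.5 * (1.0 + np.cos(np.pi * np.clip((d - half) / ramp, 0.0, 1.0)))
    pulse = np.where(d <= half, 1.0, shoulder)
    base = params.baseline_dc + params.drift_slope * idx
    al, ar = params.amplitudes(label)
    left = base + al * pulse
    right = base + ar * pulse
    if params.noise_sigma > 0:
        left = left + rng.normal(0.0, params.noise_sigma, size=n)
        right = right + rng.normal(0.0, params.noise_sigma, size=n)
    return left, right


def gen_gesture_window(
    label: str,
    params: GestureTemplateParams = GestureTemplateParams(),
    rng: np.random.Generator | None = None,
) -> GestureWindow:
    """One raw (unfiltered) two-channel window for a gesture class."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    left, right = _gesture_channels(label, params, rng)
    return GestureWindow(left, right, label=label, window_len=params.window_len)


def gen_gesture_dataset(
    n_per_class: int = 50,
    params: GestureTemplateParams = GestureTemplateParams(),
) -> list[GestureWindow]:
    """Balanced labelled dataset: n_per_class windows per gesture (default 200 total).

    Each window draws from its own child generator spawned off the master
    seed, so windows are independent yet the whole dataset is reproducible.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be at least 1")
    children = np.random.SeedSequence(params.seed).spawn(len(GESTURES) * n_per_class)
    windows = []
    k = 0
    for label in GESTURES:
        for _ in range(n_per_class):
            rng = np.random.default_rng(children[k])
            windows.append(gen_gesture_window(label, params, rng))
            k += 1
    return windows


def gen_voice_stream(
    script: list[tuple[float, str]],
    drop_prob: float = 0.0,
    confusion_prob: float = 0.0,
    seed: int = 0,
) -> list[VoiceToken]:
    """Scripted (t, word) pairs through a lossy recognizer model.

    Each token is independently dropped with ``drop_prob``, else replaced by
    a uniform random in-vocabulary word with ``confusion_prob``.
    """
    if not (0 <= drop_prob <= 1 and 0 <= confusion_prob <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    for _, word in script:
        if word not in VOCABULARY:
            raise VocabularyError(f"scripted word {word!r} not in vocabulary")
    rng = np.random.default_rng(seed)
    out: list[VoiceToken] = []
    for t, word in script:
        if rng.random() < drop_prob:
            continue
        if rng.random() < confusion_prob:
            word = VOCABULARY[rng.integers(len(VOCABULARY))]
        out.append(VoiceToken(word, t))
    return out
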