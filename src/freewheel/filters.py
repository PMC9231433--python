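"""Signal conditioning for the infrared-oculography channels.

Two first-order IIR stages run on each phototransistor channel before
classification:

* an exponential moving average (EMA) low-pass smoother,
      y(n) = w*x(n) + (1 - w)*y(n-1),
  with weighting factor w in (0, 1]; and
* a DC blocker high-pass,
      y(n) = [x(n) - x(n-1)] + alpha*y(n-1),
  whose pole coefficient alpha in (0, 1) sets the corner frequency.

Both are implemented as the literal recursions so their state and behaviour
match the embedded fixed-step loop they model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled single-channel signal (volts at source, 0-5 span)."""

    samples: np.ndarray
    fs: float = 50.0
    channel_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("trace must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class EmaParams:
    """EMA weighting factor and initial output; w=1 is the identity filter."""

    w: float = 0.2
    y_init: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.w <= 1.0:
            raise ValueError("EMA weighting factor must lie in (0, 1]")


@dataclass(frozen=True)
class DcBlockerParams:
    """DC-blocker pole and initial previous-input/previous-output state.

    ``x_init=None`` means "seed the previous input with the first sample",
    which suppresses the start-up transient on a signal with a DC offset.
    """

    alpha: float = 0.95
    x_init: float | None = None
    y_init: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("DC-blocker pole must lie in (0, 1) for stability")


def ema_filter(trace: SignalTrace, params: EmaParams = EmaParams()) -> SignalTrace:
    """Exponential moving average; output length equals input length."""
    x = trace.samples
    y = np.empty_like(x)
    prev = params.y_init
    w = params.w
    for n in range(len(x)):
        prev = w * x[n] + (1.0 - w) * prev
        y[n] = prev
    return SignalTrace(y, fs=trace.fs, channel_id=trace.channel_id)


def dc_blocker(trace: SignalTrace, params: DcBlockerParams = DcBlockerParams()) -> SignalTrace:
    """First-order IIR DC blocker; output length equals input length."""
    x = trace.samples
    y = np.empty_like(x)
    if params.x_init is not None:
        x_prev = params.x_init
    else:
        x_prev = x[0] if len(x) else 0.0
    y_prev = params.y_init
    a = params.alpha
    for n in range(len(x)):
        y_prev = (x[n] - x_prev) + a * y_prev
        x_prev = x[n]
        y[n] = y_prev
    return SignalTrace(y, fs=trace.fs, channel_id=trace.channel_id)


def condition_channel(
    trace: SignalTrace,
    ema: EmaParams = EmaParams(),
    dcb: DcBlockerParams = DcBlockerParams(),
) -> SignalTrace:
    """Smooth then remove DC: EMA first, DC blocker second."""
    return dc_blocker(ema_filter(trace, ema), dcb)
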