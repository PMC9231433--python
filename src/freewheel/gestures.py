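"""Eye-gesture classification from two-channel infrared oculography.

The interface samples two reflectance channels (one per eye region) at 50 Hz
and classifies 1.5 s windows — 75 samples per channel — into one of four
gestures: ``open``, ``close``, ``left``, ``right``.  Classification uses a
small two-layer feed-forward network (10 tanh hidden units, 4 softmax
outputs) trained by full-batch gradient descent on cross-entropy.  Pairs of
consecutive gestures then decode into drive actions:

    left,left   -> move left          right,right -> move right
    right,close -> move forward       left,close  -> move backward

Any other pair — or a pair interrupted by too many idle (eyes-open) windows —
produces no action, so spurious classifications cannot move the chair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .commands import Direction
from .filters import DcBlockerParams, EmaParams, SignalTrace, condition_channel

#: fixed label order, used for tie-breaking and model serialization
GESTURES: tuple[str, ...] = ("open", "close", "left", "right")

#: samples per channel in one classification window: 50 Hz x 1.5 s
WINDOW_LEN = 75

#: gesture-pair to drive-action table
PAIR_ACTIONS: dict[tuple[str, str], Direction] = {
    ("left", "left"): Direction.LEFT,
    ("right", "right"): Direction.RIGHT,
    ("right", "close"): Direction.FORWARD,
    ("left", "close"): Direction.BACKWARD,
}


class VocabularyError(ValueError):
    """Raised for a label outside the four-gesture alphabet."""


class WindowShapeError(ValueError):
    """Raised when channel lengths do not match the fixed window length."""


@dataclass(frozen=True)
class GestureWindow:
    """A fixed-length two-channel classification window (filtered volts)."""

    left: np.ndarray
    right: np.ndarray
    label: str | None = None
    window_len: int = WINDOW_LEN

    def __post_init__(self) -> None:
        object.__setattr__(self, "left", np.asarray(self.left, dtype=float))
        object.__setattr__(self, "right", np.asarray(self.right, dtype=float))
        if self.left.shape != (self.window_len,) or self.right.shape != (self.window_len,):
            raise WindowShapeError(
                f"channels must each hold {self.window_len} samples, got "
                f"{self.left.shape} and {self.right.shape}"
            )
        if self.label is not None and self.label not in GESTURES:
            raise VocabularyError(f"unknown gesture label {self.label!r}")


def condition_and_window(
    left: SignalTrace,
    right: SignalTrace,
    ema: EmaParams = EmaParams(),
    dcb: DcBlockerParams = DcBlockerParams(),
    label: str | None = None,
) -> GestureWindow:
    """Filter both raw channels (EMA then DC blocker) into one window."""
    if len(left) != WINDOW_LEN or len(right) != WINDOW_LEN:
        raise WindowShapeError(
            f"expected {WINDOW_LEN} samples per channel, got {len(left)}/{len(right)}"
        )
    fl = condition_channel(left, ema, dcb)
    fr = condition_channel(right, ema, dcb)
    return GestureWindow(fl.samples, fr.samples, label=label)


def window_to_features(window: GestureWindow) -> np.ndarray:
    """Concatenate left then right channel into one feature vector (length 150)."""
    return np.concatenate([window.left, window.right])


# ---------------------------------------------------------------------------
# the classifier


@dataclass
class AnnModel:
    """Two-layer feed-forward gesture classifier.

    The hidden layer applies tanh, the output layer softmax, so scores are
    nonnegative and sum to one.  Features are standardized with training-set
    statistics stored on the model.
    """

    hidden_weights: np.ndarray  # (n_hidden, n_features)
    hidden_biases: np.ndarray  # (n_hidden,)
    output_weights: np.ndarray  # (n_classes, n_hidden)
    output_biases: np.ndarray  # (n_classes,)
    feat_mean: np.ndarray  # (n_features,)
    feat_std: np.ndarray  # (n_features,)
    label_order: tuple[str, ...] = GESTURES
    train_seed: int = 0

    @property
    def n_features(self) -> int:
        return self.hidden_weights.shape[1]

    def forward(self, features: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch (n, F) or single (F,) feature array."""
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != self.n_features:
            raise WindowShapeError(
                f"feature length {x.shape[1]} != model input {self.n_features}"
            )
        z = (x - self.feat_mean) / self.feat_std
        h = np.tanh(z @ self.hidden_weights.T + self.hidden_biases)
        logits = h @ self.output_weights.T + self.output_biases
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        p = e / e.sum(axis=1, keepdims=True)
        return p if np.asarray(features).ndim == 2 else p[0]

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "label_order": list(self.label_order),
            "train_seed": int(self.train_seed),
            "hidden_weights": self.hidden_weights.tolist(),
            "hidden_biases": self.hidden_biases.tolist(),
            "output_weights": self.output_weights.tolist(),
            "output_biases": self.output_biases.tolist(),
            "feat_mean": self.feat_mean.tolist(),
            "feat_std": self.feat_std.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnnModel":
        d = json.loads(Path(path).read_text())
        return cls(
            hidden_weights=np.array(d["hidden_weights"], dtype=float),
            hidden_biases=np.array(d["hidden_biases"], dtype=float),
            output_weights=np.array(d["output_weights"], dtype=float),
            output_biases=np.array(d["output_biases"], dtype=float),
            feat_mean=np.array(d["feat_mean"], dtype=float),
            feat_std=np.array(d["feat_std"], dtype=float),
            label_order=tuple(d["label_order"]),
            train_seed=int(d["train_seed"]),
        )


class TrainingError(ValueError):
    """Raised for degenerate training sets (empty or single-label)."""


def _stratified_split(
    labels: np.ndarray, holdout_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx: list[int] = []
    test_idx: list[int] = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        idx = rng.permutation(idx)
        n_hold = int(round(holdout_fraction * len(idx)))
        n_hold = min(n_hold, len(idx) - 1)  # keep at least one training example
        test_idx.extend(idx[:n_hold])
        train_idx.extend(idx[n_hold:])
    return np.array(sorted(train_idx)), np.array(sorted(test_idx))


def train_gesture_ann(
    windows: list[GestureWindow],
    train_seed: int = 0,
    holdout_fraction: float = 0.2,
    n_hidden: int = 10,
    learning_rate: float = 0.5,
    epochs: int = 400,
) -> tuple[AnnModel, float]:
    """Train the 10-hidden / 4-output gesture network.

    Full-batch gradient descent on softmax cross-entropy with a fixed step
    and epoch cap; deterministic for a given (dataset, train_seed).  Returns
    the trained model and its held-out accuracy (1.0 when holdout_fraction
    rounds to zero examples).
    """
    if not windows:
        raise TrainingError("empty training set")
    if any(w.label is None for w in windows):
        raise TrainingError("all training windows must be labelled")
    X = np.stack([window_to_features(w) for w in windows])
    labels = np.array([w.label for w in windows])
    present = [g for g in GESTURES if g in labels]
    if len(present) < 2:
        raise TrainingError("training needs at least two distinct gesture labels")

    rng = np.random.default_rng(train_seed)
    train_idx, test_idx = _stratified_split(labels, holdout_fraction, rng)
    Xtr, ytr = X[train_idx], labels[train_idx]
    mean = Xtr.mean(axis=0)
    std = Xtr.std(axis=0)
    std[std < 1e-8] = 1.0
    Z = (Xtr - mean) / std

    n_classes = len(GESTURES)
    class_index = {g: i for i, g in enumerate(GESTURES)}
    Y = np.zeros((len(ytr), n_classes))
    Y[np.arange(len(ytr)), [class_index[g] for g in ytr]] = 1.0

    n_features = X.shape[1]
    W1 = rng.normal(0.0, 1.0 / np.sqrt(n_features), size=(n_hidden, n_features))
    b1 = np.zeros(n_hidden)
    W2 = rng.normal(0.0, 1.0 / np.sqrt(n_hidden), size=(n_classes, n_hidden))
    b2 = np.zeros(n_classes)

    n = len(Z)
    for _ in range(epochs):
        H = np.tanh(Z @ W1.T + b1)
        logits = H @ W2.T + b2
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        P = e / e.sum(axis=1, keepdims=True)
        dlogits = (P - Y) / n
        gW2 = dlogits.T @ H
        gb2 = dlogits.sum(axis=0)
        dH = dlogits @ W2
        dZ1 = dH * (1.0 - H**2)
        gW1 = dZ1.T @ Z
        gb1 = dZ1.sum(axis=0)
        W2 -= learning_rate * gW2
        b2 -= learning_rate * gb2
        W1 -= learning_rate * gW1
        b1 -= learning_rate * gb1

    model = AnnModel(W1, b1, W2, b2, mean, std, GESTURES, train_seed)
    if len(test_idx):
        probs = model.forward(X[test_idx])
        pred = np.array([GESTURES[i] for i in probs.argmax(axis=1)])
        accuracy = float(np.mean(pred == labels[test_idx]))
    else:
        accuracy = 1.0
    return model, accuracy


def classify_gesture(model: AnnModel, window: GestureWindow) -> tuple[str, np.ndarray]:
    """Label and score vector for one window; ties break by label order."""
    scores = model.forward(window_to_features(window))
    return model.label_order[int(np.argmax(scores))], scores


# ---------------------------------------------------------------------------
# sequence decoding


@dataclass
class GestureSequenceDecoder:
    """Stateful pair decoder: two non-idle gestures form one command.

    ``open`` is the idle gesture.  A pending first gesture expires after more
    than ``timeout_windows`` consecutive idle windows.  Pairs outside the
    action table reset the decoder and emit nothing.
    """

    timeout_windows: int = 3
    pending: str | None = None
    idle_count: int = 0

    def step(self, label: str) -> Direction | None:
        if label not in GESTURES:
            raise VocabularyError(f"unknown gesture label {label!r}")
        if label == "open":
            if self.pending is not None:
                self.idle_count += 1
                if self.idle_count > self.timeout_windows:
                    self.reset()
            return None
        if self.pending is None:
            self.pending = label
            self.idle_count = 0
            return None
        pair = (self.pending, label)
        self.reset()
        return PAIR_ACTIONS.get(pair)

    def reset(self) -> None:
        self.pending = None
        self.idle_count = 0


def decode_gesture_sequence(
    labels, timeout_windows: int = 3
) -> list[tuple[int, Direction]]:
    """Decode a stream of window labels into (window index, action) events."""
    decoder = GestureSequenceDecoder(timeout_windows=timeout_windows)
    events = []
    for i, lab in enumerate(labels):
        action = decoder.step(lab)
        if action is not None:
            events.append((i, action))
    return events
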