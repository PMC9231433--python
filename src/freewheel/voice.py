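"""Voice-command grammar: an eight-word attention/orientation protocol.

The recognizer vocabulary holds four *attention* words — ``stop``, ``move``,
``go``, ``run`` — and four *orientation* words — ``forward``, ``backward``,
``left``, ``right``.  An attention word arms a motion mode (move: 1 s timed;
go: 2 s timed; run: continuous); the next orientation word fires a drive
command in that mode.  ``stop`` halts everything.  An orientation word with
no armed attention is ignored, so stray recognizer output cannot move the
chair.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .commands import STOP, Direction, DriveCommand, Mode, StopCommand

ATTENTION_WORDS = ("stop", "move", "go", "run")
ORIENTATION_WORDS = ("forward", "backward", "left", "right")
VOCABULARY = ATTENTION_WORDS + ORIENTATION_WORDS

#: mode and duration armed by each non-stop attention word
ATTENTION_MODES: dict[str, tuple[Mode, float | None]] = {
    "move": (Mode.TIMED, 1.0),
    "go": (Mode.TIMED, 2.0),
    "run": (Mode.CONTINUOUS, None),
}


class UnrecognizedTokenError(ValueError):
    """Raised for a word outside the eight-command vocabulary."""


class InputOrderError(ValueError):
    """Raised when a token stream is not time-ordered."""


@dataclass(frozen=True)
class VoiceToken:
    word: str
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.word not in VOCABULARY:
            raise UnrecognizedTokenError(f"unrecognized voice command {self.word!r}")

    @property
    def is_attention(self) -> bool:
        return self.word in ATTENTION_WORDS


def parse_voice_token(text: str, t: float = 0.0) -> VoiceToken:
    """Case-insensitive, whitespace-trimmed match against the vocabulary."""
    word = text.strip().lower()
    if word not in VOCABULARY:
        raise UnrecognizedTokenError(f"unrecognized voice command {text!r}")
    return VoiceToken(word, t)


@dataclass(frozen=True)
class GrammarState:
    """FSM state: at most one pending attention word; stop clears everything."""

    pending_attention: str | None = None
    active_command: DriveCommand | None = None
    halted: bool = False


def grammar_step(
    state: GrammarState, token: VoiceToken
) -> tuple[GrammarState, DriveCommand | StopCommand | None]:
    """Advance the grammar by one token; return (new state, emission).

    * ``stop`` halts, clears pending and active, and emits a StopCommand.
    * another attention word replaces any pending one (no emission).
    * an orientation word with a pending attention emits a DriveCommand in
      the armed mode and clears the pending slot; with none pending it is
      silently ignored.
    """
    if token.word == "stop":
        return GrammarState(halted=True), STOP
    if token.is_attention:
        return replace(state, pending_attention=token.word, halted=False), None
    if state.pending_attention is None:
        return state, None
    mode, duration = ATTENTION_MODES[state.pending_attention]
    cmd = DriveCommand(Direction(token.word), mode, duration)
    return GrammarState(pending_attention=None, active_command=cmd), cmd


@dataclass(frozen=True)
class CommandInterval:
    """One activation on the session timeline; t_off None means still active."""

    direction: Direction
    mode: Mode
    t_on: float
    t_off: float | None


def run_voice_session(tokens: list[VoiceToken]) -> list[CommandInterval]:
    """Fold the grammar over a time-ordered token stream into a timeline.

    Timed commands deactivate after their duration; continuous commands run
    until superseded by the next emitted command or a stop.
    """
    times = [tok.t for tok in tokens]
    if any(b < a for a, b in zip(times, times[1:])):
        raise InputOrderError("voice tokens must be time-ordered")

    state = GrammarState()
    timeline: list[CommandInterval] = []

    def close_active(at: float) -> None:
        if timeline and (timeline[-1].t_off is None or timeline[-1].t_off > at):
            last = timeline[-1]
            timeline[-1] = CommandInterval(last.direction, last.mode, last.t_on, at)

    for tok in tokens:
        state, emission = grammar_step(state, tok)
        if isinstance(emission, StopCommand):
            close_active(tok.t)
        elif isinstance(emission, DriveCommand):
            close_active(tok.t)
            t_off = tok.t + emission.duration_s if emission.mode is Mode.TIMED else None
            timeline.append(CommandInterval(emission.direction, emission.mode, tok.t, t_off))
    return timeline
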