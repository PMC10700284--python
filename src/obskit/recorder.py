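"""Replay a timestamped keypress stream into a finalized session record.

The recorder is a small state machine over raw key tokens:

* ``ESC`` starts the session (from idle).
* ``LCTRL`` toggles pause; the session clock freezes during a pause, so
  event times automatically exclude paused wall time.
* A bound frequency key commits one event at the current session clock.
* A bound duration key opens its behavior episode if closed, and commits
  the episode on the next press.
* ``BKSP`` deletes the most recently *committed* event (commit order, not
  timestamp order); ``RCTRL`` restores it.  Committing a new event clears
  the redo stack, as in an ordinary editor.
* An optional session cap ends the session the moment the clock reaches
  it; tokens arriving after that are absorbed without effect.

Keys pressed while idle or paused are ignored — the session clock is not
running, so there is no session time to attach them to.  The recorder is a
pure function of the token stream: replaying the same stream always yields
the same record.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .errors import RecorderError
from .ksf import KeystrokeSchema
from .session import (
    DurationEvent,
    FrequencyEvent,
    PauseInterval,
    SessionInfo,
    SessionRecord,
    frame_for_time,
)

logger = logging.getLogger(__name__)

#: Canonical spellings of the reserved control symbols in token logs.
ESC = "ESC"
LCTRL = "LCTRL"
RCTRL = "RCTRL"
BKSP = "BKSP"
CONTROL_SYMBOLS = frozenset({ESC, LCTRL, RCTRL, BKSP})


@dataclass(frozen=True)
class KeyPressToken:
    """One raw key input: a printable key or a control symbol, at wall time."""

    key: str
    wall_time: float


@dataclass(frozen=True)
class RecorderConfig:
    """Optional interval-timer and session-cap settings, in seconds."""

    interval_s: Optional[float] = None
    cap_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.interval_s is not None and self.interval_s <= 0:
            raise RecorderError("interval_s must be positive when set")
        if self.cap_s is not None and self.cap_s <= 0:
            raise RecorderError("cap_s must be positive when set")


Event = Union[FrequencyEvent, DurationEvent]


@dataclass
class RecorderState:
    """Mutable state threaded through :func:`process_token`.

    ``process_token`` mutates and returns the same object; create a fresh
    state per replay.
    """

    config: RecorderConfig = field(default_factory=RecorderConfig)
    phase: str = "idle"  # idle | running | paused | ended
    session_start_wall: Optional[float] = None
    pauses: list[PauseInterval] = field(default_factory=list)
    open_pause_start: Optional[float] = None
    open_durations: dict[str, float] = field(default_factory=dict)
    committed: list[Event] = field(default_factory=list)
    undo_stack: list[Event] = field(default_factory=list)
    last_wall: float = -math.inf
    end_clock: Optional[float] = None
    end_wall: Optional[float] = None


def session_clock(state: RecorderState, wall_time: float) -> float:
    """Session seconds at *wall_time*: elapsed wall time minus paused spans.

    During a pause the clock is frozen at its value when the pause began.
    """
    if state.phase == "idle" or state.session_start_wall is None:
        raise RecorderError("session clock queried before the session started")
    if wall_time < state.session_start_wall:
        raise RecorderError(
            f"wall time {wall_time} precedes session start {state.session_start_wall}"
        )
    paused = 0.0
    for p in state.pauses:
        lo = max(p.wall_start, state.session_start_wall)
        hi = min(p.wall_end, wall_time)
        if hi > lo:
            paused += hi - lo
    if state.open_pause_start is not None and wall_time > state.open_pause_start:
        paused += wall_time - state.open_pause_start
    return wall_time - state.session_start_wall - paused


def _wall_for_clock(state: RecorderState, clock: float) -> float:
    """Earliest wall time at which the session clock reads *clock*."""
    assert state.session_start_wall is not None
    # Each pause that begins before the target wall time pushes it later.
    wall = state.session_start_wall + clock
    for p in sorted(state.pauses, key=lambda p: p.wall_start):
        if p.wall_start < wall:
            wall += p.length
    return wall


def _commit(state: RecorderState, event: Event) -> None:
    state.committed.append(event)
    state.undo_stack.clear()  # a new commit invalidates redo history


def _end_at_cap(state: RecorderState) -> None:
    cap = state.config.cap_s
    assert cap is not None
    state.end_wall = _wall_for_clock(state, cap)
    # An open pause necessarily began at or after the cap-crossing wall time
    # (the clock is frozen while paused), so it falls outside the session.
    state.open_pause_start = None
    state.pauses = [p for p in state.pauses if p.wall_start < state.end_wall]
    state.end_clock = cap
    state.phase = "ended"


def process_token(
    state: RecorderState, token: KeyPressToken, schema: KeystrokeSchema
) -> RecorderState:
    """Advance the recorder by one token.  Returns the (mutated) state.

    All inputs are absorbed: unbound keys and unknown control symbols are
    ignored (the latter with a logged warning), and tokens arriving after
    the session ended have no effect.
    """
    if token.wall_time < state.last_wall:
        raise RecorderError(
            f"token stream went backwards in time: {token.wall_time} < {state.last_wall}"
        )
    state.last_wall = token.wall_time

    # Session cap: the session ends the instant the clock reaches the cap,
    # before this token takes effect.
    if (
        state.phase in ("running", "paused")
        and state.config.cap_s is not None
        and session_clock(state, token.wall_time) >= state.config.cap_s
    ):
        _end_at_cap(state)

    if state.phase == "ended":
        return state

    key = token.key
    if key == ESC:
        if state.phase == "idle":
            state.phase = "running"
            state.session_start_wall = token.wall_time
        return state

    if state.phase == "idle":
        return state  # nothing but ESC matters before the session starts

    if key == LCTRL:
        if state.phase == "running":
            state.phase = "paused"
            state.open_pause_start = token.wall_time
        else:  # paused -> resume
            assert state.open_pause_start is not None
            if token.wall_time > state.open_pause_start:
                state.pauses.append(
                    PauseInterval(state.open_pause_start, token.wall_time)
                )
            state.open_pause_start = None
            state.phase = "running"
        return state

    if key == BKSP:
        if state.committed:
            state.undo_stack.append(state.committed.pop())
        return state

    if key == RCTRL:
        if state.undo_stack:
            state.committed.append(state.undo_stack.pop())
        return state

    if key in CONTROL_SYMBOLS or len(key) != 1:
        logger.warning("ignoring unknown control symbol %r", key)
        return state

    if state.phase != "running":
        return state  # bound keys during a pause are ignored, not queued

    binding = schema.binding_for_key(key)
    if binding is None:
        return state

    t = session_clock(state, token.wall_time)
    if binding.kind == "frequency":
        _commit(state, FrequencyEvent(binding.behavior, t))
    else:
        tag = binding.behavior
        if tag in state.open_durations:
            start = state.open_durations.pop(tag)
            _commit(state, DurationEvent(tag, start, t))
        else:
            state.open_durations[tag] = t
    return state


def interval_marks(duration_s: float, interval_s: float) -> list[float]:
    """Interval-timer mark times: every positive multiple of *interval_s*
    that is ≤ *duration_s* (for discontinuous measurement strategies)."""
    if interval_s <= 0:
        raise RecorderError(f"interval must be positive, got {interval_s}")
    if duration_s <= 0:
        raise RecorderError(f"duration must be positive, got {duration_s}")
    n = int(math.floor(duration_s / interval_s + 1e-9))
    return [i * interval_s for i in range(1, n + 1)]


def finalize_session(
    state: RecorderState, info: SessionInfo, schema: KeystrokeSchema
) -> SessionRecord:
    """Close the session and produce a validated :class:`SessionRecord`.

    Open duration episodes are closed at the final session time; the undo
    stack is discarded; ``info.duration`` is set to the final session clock
    so that wall span = duration + total pause time, exactly.
    """
    if state.phase == "idle":
        raise RecorderError("cannot finalize a session that never started")

    if state.phase == "ended":
        final_clock = state.end_clock
        assert final_clock is not None
    else:
        # A pause still open at finalize counts as pause up to the last token.
        if state.open_pause_start is not None and state.last_wall > state.open_pause_start:
            state.pauses.append(PauseInterval(state.open_pause_start, state.last_wall))
            state.open_pause_start = None
        final_clock = session_clock(state, max(state.last_wall,
                                               state.session_start_wall))

    for tag, start in sorted(state.open_durations.items()):
        state.committed.append(DurationEvent(tag, start, final_clock))
    state.open_durations.clear()
    state.undo_stack.clear()

    freq = sorted(
        (e for e in state.committed if isinstance(e, FrequencyEvent)),
        key=lambda e: e.t,
    )
    dur = sorted(
        (e for e in state.committed if isinstance(e, DurationEvent)),
        key=lambda e: e.start,
    )

    fps = info.video_fps
    if fps is not None:
        freq = [replace(e, frame=frame_for_time(e.t, fps)) for e in freq]
        dur = [
            replace(e, start_frame=frame_for_time(e.start, fps),
                    end_frame=frame_for_time(e.end, fps))
            for e in dur
        ]

    info = replace(info, duration=final_clock)
    return SessionRecord(
        info=info,
        freq_events=tuple(freq),
        dur_events=tuple(dur),
        pauses=tuple(sorted(state.pauses, key=lambda p: p.wall_start)),
        schema=schema,
    )


def replay_tokens(
    tokens: Iterable[KeyPressToken],
    schema: KeystrokeSchema,
    config: RecorderConfig | None = None,
) -> RecorderState:
    """Feed a whole token stream through a fresh recorder state."""
    state = RecorderState(config=config or RecorderConfig())
    for tok in tokens:
        process_token(state, tok, schema)
    return state


def record_session(
    tokens: Iterable[KeyPressToken],
    info: SessionInfo,
    schema: KeystrokeSchema,
    config: RecorderConfig | None = None,
) -> SessionRecord:
    """Replay *tokens* and finalize: the one-call path from log to record."""
    return finalize_session(replay_tokens(tokens, schema, config), info, schema)


# ---------------------------------------------------------------------------
# Token-log I/O: CSV (wall_time,key) or JSON lines ({"wall_time":..,"key":..})
# ---------------------------------------------------------------------------

def write_token_log(tokens: Sequence[KeyPressToken], path: str | Path) -> Path:
    p = Path(path)
    if p.suffix in (".jsonl", ".json"):
        with open(p, "w", encoding="utf-8") as fh:
            for tok in tokens:
                fh.write(json.dumps({"wall_time": tok.wall_time, "key": tok.key}))
                fh.write("\n")
    else:
        with open(p, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["wall_time", "key"])
            for tok in tokens:
                writer.writerow([repr(tok.wall_time), tok.key])
    return p


def read_token_log(path: str | Path) -> list[KeyPressToken]:
    p = Path(path)
    if not p.is_file():
        raise RecorderError(f"token log not found: {p}")
    tokens: list[KeyPressToken] = []
    if p.suffix in (".jsonl", ".json"):
        with open(p, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                d = json.loads(line)
                tokens.append(KeyPressToken(str(d["key"]), float(d["wall_time"])))
    else:
        with open(p, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "wall_time" not in reader.fieldnames:
                raise RecorderError(f"token log {p} lacks a wall_time,key header")
            for row in reader:
                tokens.append(KeyPressToken(row["key"], float(row["wall_time"])))
    return tokens
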