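"""Session data model, JSON persistence, naming, and timeline arithmetic.

A session is one observation period.  Its record is self-contained: the
patient/session metadata, every scored event, every pause, and a snapshot
of the keystroke schema in force are embedded in a single JSON document,
so a session file can be processed with nothing else on disk.

Times come in two flavors and the distinction matters everywhere:

* *wall-clock* seconds — real elapsed time (pauses are stored this way);
* *session* seconds — the session clock, which freezes during pauses.
  All event times are session seconds.

File naming follows the convention
``{session number} {assessment[:2]} {condition[:2]}{DDMYYYY}{_R?}``
where the date renders as a two-digit zero-padded day, an unpadded month
numeral and a four-digit year (5 March 2023 → ``0532023``).  The month is
the only variable-width field, so a parser disambiguates by total length.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from .errors import SessionValidationError
from .ksf import KeystrokeSchema

FORMAT_VERSION = 1

#: Default clinical phases.
PHASES = ("Assessment", "Treatment")

#: The video timeline seek step, in seconds, per invocation.
VIDEO_SEEK_STEP_S = 1.0


# ---------------------------------------------------------------------------
# Event and metadata types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyEvent:
    """One discrete scored instance of a behavior at session time ``t``."""

    tag: str
    t: float
    frame: Optional[int] = None

    def __post_init__(self) -> None:
        if self.t < 0:
            raise SessionValidationError(f"event {self.tag!r} has negative time {self.t}")
        if self.frame is not None and self.frame < 0:
            raise SessionValidationError(f"event {self.tag!r} has negative frame index")

    @property
    def time(self) -> float:
        return self.t


@dataclass(frozen=True)
class DurationEvent:
    """A timed behavior episode spanning [start, end] in session seconds."""

    tag: str
    start: float
    end: float
    start_frame: Optional[int] = None
    end_frame: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise SessionValidationError(
                f"duration event {self.tag!r} has invalid span [{self.start}, {self.end}]"
            )

    @property
    def time(self) -> float:
        return self.start

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class PauseInterval:
    """A paused span in wall-clock seconds (the session clock is frozen here)."""

    wall_start: float
    wall_end: float

    def __post_init__(self) -> None:
        if not self.wall_start < self.wall_end:
            raise SessionValidationError(
                f"pause interval [{self.wall_start}, {self.wall_end}] is empty or reversed"
            )

    @property
    def length(self) -> float:
        return self.wall_end - self.wall_start


@dataclass(frozen=True)
class SessionInfo:
    mrn: str = ""
    assessment: str = ""
    condition: str = ""
    therapist: str = ""
    data_recorder: str = ""
    concern: str = ""
    phase: str = "Assessment"
    session_number: str = "1"
    is_reliability: bool = False
    start_datetime: datetime = datetime(2023, 1, 1, 0, 0, 0)
    duration: float = 0.0
    video_fps: Optional[float] = None

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise SessionValidationError(
                f"phase {self.phase!r} is not one of {PHASES}"
            )
        if self.duration < 0:
            raise SessionValidationError("session duration must be non-negative")
        if self.video_fps is not None and self.video_fps <= 0:
            raise SessionValidationError("video_fps must be positive when present")


_INFO_FIELDS = (
    "mrn", "assessment", "condition", "therapist", "data_recorder", "concern",
    "phase", "session_number", "is_reliability", "start_datetime", "duration",
    "video_fps",
)


@dataclass(frozen=True)
class SessionRecord:
    """A complete, self-contained observation session."""

    info: SessionInfo
    freq_events: tuple[FrequencyEvent, ...] = ()
    dur_events: tuple[DurationEvent, ...] = ()
    pauses: tuple[PauseInterval, ...] = ()
    schema: KeystrokeSchema = field(default_factory=lambda: KeystrokeSchema("empty"))
    physio_ref: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "freq_events", tuple(self.freq_events))
        object.__setattr__(self, "dur_events", tuple(self.dur_events))
        object.__setattr__(self, "pauses", tuple(self.pauses))
        self.validate()

    def validate(self) -> None:
        for seq, label in ((self.freq_events, "frequency"), (self.dur_events, "duration")):
            last = -math.inf
            for ev in seq:
                if ev.time < last:
                    raise SessionValidationError(
                        f"{label} events are not sorted by time (at {ev.tag!r} t={ev.time})"
                    )
                last = ev.time
                if not self.schema.has_behavior(ev.tag):
                    raise SessionValidationError(
                        f"event tag {ev.tag!r} not present in embedded schema "
                        f"{self.schema.name!r}"
                    )
        for ev in self.freq_events:
            if self.schema.kind_of(ev.tag) != "frequency":
                raise SessionValidationError(
                    f"tag {ev.tag!r} is duration-bound but appears as a frequency event"
                )
            if ev.t > self.info.duration:
                raise SessionValidationError(
                    f"event {ev.tag!r} at t={ev.t} exceeds session duration "
                    f"{self.info.duration}"
                )
        for ev in self.dur_events:
            if self.schema.kind_of(ev.tag) != "duration":
                raise SessionValidationError(
                    f"tag {ev.tag!r} is frequency-bound but appears as a duration event"
                )
            if ev.end > self.info.duration:
                raise SessionValidationError(
                    f"duration event {ev.tag!r} ends at {ev.end}, past session duration "
                    f"{self.info.duration}"
                )
        prev_end = -math.inf
        for p in self.pauses:
            if p.wall_start < prev_end:
                raise SessionValidationError("pause intervals overlap or are unordered")
            prev_end = p.wall_end
        if self.schema.conditions and self.info.condition not in self.schema.conditions:
            raise SessionValidationError(
                f"condition {self.info.condition!r} not among schema conditions "
                f"{list(self.schema.conditions)}"
            )

    @property
    def total_pause_s(self) -> float:
        return sum(p.length for p in self.pauses)

    def events_for_tag(self, tag: str):
        kind = self.schema.kind_of(tag)
        if kind == "frequency":
            return tuple(e for e in self.freq_events if e.tag == tag)
        return tuple(e for e in self.dur_events if e.tag == tag)

    def all_events_sorted(self):
        """Every event, frequency and duration together, ordered by onset."""
        return tuple(sorted(self.freq_events + self.dur_events,
                            key=lambda e: (e.time, e.tag)))


# ---------------------------------------------------------------------------
# File naming
# ---------------------------------------------------------------------------

def _render_date(d: date) -> str:
    return f"{d.day:02d}{d.month}{d.year:04d}"


def session_filename(info: SessionInfo) -> str:
    """Render the session file name (without extension) for *info*.

    ``"{number} {assessment[:2]} {condition[:2]}{DDMYYYY}{_R?}"`` — e.g.
    session 1, assessment "Functional Analysis", condition "Tangible",
    5 March 2023, reliability → ``"1 Fu Ta0532023_R"``.
    """
    if len(info.assessment) < 2:
        raise SessionValidationError(
            f"assessment {info.assessment!r} must have at least 2 characters"
        )
    if len(info.condition) < 2:
        raise SessionValidationError(
            f"condition {info.condition!r} must have at least 2 characters"
        )
    suffix = "_R" if info.is_reliability else ""
    return (
        f"{info.session_number} {info.assessment[:2]} "
        f"{info.condition[:2]}{_render_date(info.start_datetime.date())}{suffix}"
    )


_NAME_RE = re.compile(
    r"^(?P<number>.+) (?P<assessment>..) (?P<condition>..)"
    r"(?P<datedigits>\d{7,8})(?P<rel>_R)?$"
)


@dataclass(frozen=True)
class ParsedSessionName:
    session_number: str
    assessment_prefix: str
    condition_prefix: str
    session_date: date
    is_reliability: bool


def parse_session_filename(name: str) -> ParsedSessionName:
    """Invert :func:`session_filename`.

    The date block is 7 or 8 digits: a fixed two-digit day, a one- or
    two-digit month, and a four-digit year; the total length decides the
    month width.
    """
    m = _NAME_RE.match(name)
    if not m:
        raise SessionValidationError(f"unparseable session file name: {name!r}")
    digits = m.group("datedigits")
    day = int(digits[:2])
    year = int(digits[-4:])
    month = int(digits[2:-4])
    try:
        d = date(year, month, day)
    except ValueError as exc:
        raise SessionValidationError(f"invalid date in session name {name!r}") from exc
    return ParsedSessionName(
        session_number=m.group("number"),
        assessment_prefix=m.group("assessment"),
        condition_prefix=m.group("condition"),
        session_date=d,
        is_reliability=m.group("rel") is not None,
    )


# ---------------------------------------------------------------------------
# JSON persistence
# ---------------------------------------------------------------------------

def _info_to_dict(info: SessionInfo) -> dict:
    d = {}
    for name in _INFO_FIELDS:
        v = getattr(info, name)
        if isinstance(v, datetime):
            v = v.isoformat()
        d[name] = v
    return d


def _info_from_dict(d: dict) -> SessionInfo:
    missing = [f for f in _INFO_FIELDS if f not in d]
    if missing:
        raise SessionValidationError(f"session info missing field(s): {missing}")
    kwargs = dict(d)
    kwargs["start_datetime"] = datetime.fromisoformat(d["start_datetime"])
    return SessionInfo(**{k: kwargs[k] for k in _INFO_FIELDS})


def record_to_dict(record: SessionRecord) -> dict:
    """Stable-order dictionary form of a session record."""
    return {
        "format_version": FORMAT_VERSION,
        "info": _info_to_dict(record.info),
        "freq_events": [
            {"tag": e.tag, "t": e.t, "frame": e.frame} for e in record.freq_events
        ],
        "dur_events": [
            {"tag": e.tag, "start": e.start, "end": e.end,
             "start_frame": e.start_frame, "end_frame": e.end_frame}
            for e in record.dur_events
        ],
        "pauses": [
            {"wall_start": p.wall_start, "wall_end": p.wall_end} for p in record.pauses
        ],
        "schema": record.schema.to_dict(),
        "physio_ref": record.physio_ref,
    }


def record_from_dict(doc: dict) -> SessionRecord:
    for required in ("info", "freq_events", "dur_events", "pauses", "schema"):
        if required not in doc:
            raise SessionValidationError(f"session JSON missing field {required!r}")
    schema = KeystrokeSchema.from_dict(doc["schema"])
    freq = tuple(
        FrequencyEvent(e["tag"], e["t"], e.get("frame")) for e in doc["freq_events"]
    )
    dur = tuple(
        DurationEvent(e["tag"], e["start"], e["end"],
                      e.get("start_frame"), e.get("end_frame"))
        for e in doc["dur_events"]
    )
    pauses = tuple(
        PauseInterval(p["wall_start"], p["wall_end"]) for p in doc["pauses"]
    )
    return SessionRecord(
        info=_info_from_dict(doc["info"]),
        freq_events=freq,
        dur_events=dur,
        pauses=pauses,
        schema=schema,
        physio_ref=doc.get("physio_ref"),
    )


def write_session_json(record: SessionRecord, out_path: str | Path) -> Path:
    """Write the record as one self-contained UTF-8 JSON document."""
    path = Path(out_path)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(record_to_dict(record), fh, indent=2, ensure_ascii=False)
            fh.write("\n")
    except OSError as exc:
        raise SessionValidationError(f"cannot write session JSON to {path}: {exc}") from exc
    return path


def read_session_json(path: str | Path) -> SessionRecord:
    """Load and re-validate a session record from JSON."""
    p = Path(path)
    if not p.is_file():
        raise SessionValidationError(f"session file not found: {p}")
    try:
        with open(p, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SessionValidationError(f"malformed session JSON in {p}: {exc}") from exc
    return record_from_dict(doc)


# ---------------------------------------------------------------------------
# Session-number classification
# ---------------------------------------------------------------------------

Classification = Literal["new_primary", "duplicate_needs_reliability", "bypass"]


def classify_session_number(
    existing_primary_numbers: Iterable[str], candidate: str
) -> Classification:
    """Decide how a candidate session number relates to existing primaries.

    Integer session numbers participate in the duplicate check: a number
    already used by a primary session flags the new session as the
    reliability pass of that session.  Any non-integer number (dates,
    letter-suffixed labels, ...) bypasses the check entirely.
    """
    try:
        cand = int(candidate)
    except (TypeError, ValueError):
        return "bypass"
    for n in existing_primary_numbers:
        try:
            if int(n) == cand:
                return "duplicate_needs_reliability"
        except (TypeError, ValueError):
            continue
    return "new_primary"


# ---------------------------------------------------------------------------
# Video timeline arithmetic
# ---------------------------------------------------------------------------

def frame_for_time(t: float, fps: float) -> int:
    """Video frame index on screen at session time *t*: ``floor(t * fps)``."""
    if fps <= 0:
        raise SessionValidationError(f"fps must be positive, got {fps}")
    if t < 0:
        raise SessionValidationError(f"time must be non-negative, got {t}")
    return int(math.floor(t * fps))


def seek_video(position_s: float, direction: Literal["forward", "backward"],
               duration_s: Optional[float] = None) -> float:
    """Move the video position by exactly one second, clamped to the timeline."""
    if direction == "forward":
        pos = position_s + VIDEO_SEEK_STEP_S
    elif direction == "backward":
        pos = position_s - VIDEO_SEEK_STEP_S
    else:
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    pos = max(0.0, pos)
    if duration_s is not None:
        pos = min(pos, duration_s)
    return pos
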