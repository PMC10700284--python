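"""On-disk project hierarchy, recent-projects config, saving and exports.

Projects live under a root directory as
``root/<project>/<patient>/<concern> <phase>/`` with the four standard
subfolders ``Export``, ``Graph``, ``KSF`` and ``Raw Data`` (the latter
split into ``Primary`` and ``Reliability``).  A small JSON registry in
each patient folder records the medical record number and the concerns
seen so far.

The recent-projects list keeps at most the 20 most recently used project
paths, most recent first, dropping the oldest beyond capacity.

Nothing here overwrites silently: saving a session whose file already
exists raises unless ``force`` is passed.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import openpyxl

from .errors import StorageError
from .session import (
    DurationEvent,
    FrequencyEvent,
    SessionRecord,
    _INFO_FIELDS,
    _info_to_dict,
    read_session_json,
    session_filename,
    write_session_json,
)

PHASE_SUBDIRS = ("Export", "Graph", "KSF", "Raw Data")
RAW_SUBDIRS = ("Primary", "Reliability")
RECENT_PROJECTS_CAPACITY = 20
PATIENT_REGISTRY = "patient.json"
ANALYSIS_SHEET = "Sessions"


@dataclass(frozen=True)
class ProjectLayout:
    root: Path
    project_name: str
    patient_name: str
    concern: str
    phase: str

    @property
    def project_dir(self) -> Path:
        return self.root / self.project_name

    @property
    def patient_dir(self) -> Path:
        return self.project_dir / self.patient_name

    @property
    def phase_dir(self) -> Path:
        return self.patient_dir / f"{self.concern} {self.phase}"

    @property
    def raw_dir(self) -> Path:
        return self.phase_dir / "Raw Data"

    def raw_subdir(self, is_reliability: bool) -> Path:
        return self.raw_dir / ("Reliability" if is_reliability else "Primary")

    @property
    def export_dir(self) -> Path:
        return self.phase_dir / "Export"

    @property
    def ksf_dir(self) -> Path:
        return self.phase_dir / "KSF"

    @property
    def graph_dir(self) -> Path:
        return self.phase_dir / "Graph"


def init_phase_dirs(
    root: str | Path,
    project: str,
    patient: str,
    concern: str,
    phase: str,
    mrn: str = "",
) -> ProjectLayout:
    """Create (idempotently) the full directory tree for a concern phase.

    Also creates or updates the patient registry JSON with the MRN and the
    concern list.
    """
    for name, label in ((project, "project"), (patient, "patient"),
                        (concern, "concern"), (phase, "phase")):
        if not name or not str(name).strip():
            raise StorageError(f"{label} name must be non-empty")
    root = Path(root)
    if not root.is_dir():
        raise StorageError(f"project root does not exist: {root}")
    layout = ProjectLayout(root, project, patient, concern, phase)
    try:
        for sub in PHASE_SUBDIRS:
            (layout.phase_dir / sub).mkdir(parents=True, exist_ok=True)
        for sub in RAW_SUBDIRS:
            (layout.raw_dir / sub).mkdir(exist_ok=True)
    except OSError as exc:
        raise StorageError(f"cannot create project tree under {root}: {exc}") from exc

    reg_path = layout.patient_dir / PATIENT_REGISTRY
    registry = {"patient": patient, "mrn": mrn, "concerns": []}
    if reg_path.is_file():
        with open(reg_path, encoding="utf-8") as fh:
            registry.update(json.load(fh))
        if mrn:
            registry["mrn"] = mrn
    if concern not in registry["concerns"]:
        registry["concerns"].append(concern)
    with open(reg_path, "w", encoding="utf-8") as fh:
        json.dump(registry, fh, indent=2)
        fh.write("\n")
    return layout


# ---------------------------------------------------------------------------
# Recent projects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecentProjects:
    """Most-recent-first project paths, capped at 20, no duplicates."""

    paths: tuple[str, ...] = ()
    capacity: int = RECENT_PROJECTS_CAPACITY

    def __post_init__(self) -> None:
        object.__setattr__(self, "paths", tuple(self.paths))
        if len(set(self.paths)) != len(self.paths):
            raise StorageError("recent-projects list contains duplicates")
        if len(self.paths) > self.capacity:
            raise StorageError(
                f"recent-projects list exceeds capacity {self.capacity}"
            )

    def __len__(self) -> int:
        return len(self.paths)


def update_recent_projects(
    state: RecentProjects, project_path: str | Path
) -> RecentProjects:
    """Move/insert *project_path* at the front, dropping the oldest past 20."""
    p = str(project_path)
    rest = tuple(x for x in state.paths if x != p)
    new = (p,) + rest
    return replace(state, paths=new[: state.capacity])


def load_config(config_path: str | Path) -> RecentProjects:
    """Load the recent-projects configuration file (absent file → empty)."""
    p = Path(config_path)
    if not p.is_file():
        return RecentProjects()
    with open(p, encoding="utf-8") as fh:
        doc = json.load(fh)
    return RecentProjects(paths=tuple(doc.get("recent_projects", ())))


def save_config(state: RecentProjects, config_path: str | Path) -> Path:
    p = Path(config_path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w", encoding="utf-8") as fh:
        json.dump({"recent_projects": list(state.paths)}, fh, indent=2)
        fh.write("\n")
    return p


# ---------------------------------------------------------------------------
# Session persistence
# ---------------------------------------------------------------------------

def save_session(
    record: SessionRecord, layout: ProjectLayout, force: bool = False
) -> Path:
    """Save a session JSON under Raw Data/Primary or /Reliability.

    The file is named by the session naming convention.  An existing file
    of the same name raises :class:`StorageError` unless *force* is given
    — never a silent overwrite.
    """
    target_dir = layout.raw_subdir(record.info.is_reliability)
    if not target_dir.is_dir():
        raise StorageError(
            f"layout not initialized: {target_dir} missing; run init_phase_dirs first"
        )
    out = target_dir / (session_filename(record.info) + ".json")
    if out.exists() and not force:
        raise StorageError(f"session file already exists: {out} (use force to replace)")
    write_session_json(record, out)
    if record.physio_ref:
        src = Path(record.physio_ref)
        if src.is_file():
            dest = target_dir / (out.stem + src.suffix)
            if not dest.exists() or force:
                dest.write_bytes(src.read_bytes())
    return out


def iter_saved_sessions(
    layout: ProjectLayout, include_reliability: bool = False
) -> list[tuple[Path, SessionRecord]]:
    dirs = [layout.raw_subdir(False)]
    if include_reliability:
        dirs.append(layout.raw_subdir(True))
    out = []
    for d in dirs:
        if not d.is_dir():
            continue
        for p in sorted(d.glob("*.json")):
            out.append((p, read_session_json(p)))
    return out


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------

_EVENT_HEADER = ("Tag", "Kind", "Start (s)", "End (s)")


def export_csv(record: SessionRecord, out_path: str | Path) -> Path:
    """Export one session as CSV: info key/value block, then events in order."""
    p = Path(out_path)
    try:
        fh = open(p, "w", encoding="utf-8", newline="")
    except OSError as exc:
        raise StorageError(f"cannot write CSV to {p}: {exc}") from exc
    with fh:
        writer = csv.writer(fh)
        for key, value in _info_to_dict(record.info).items():
            writer.writerow([key, value])
        writer.writerow([])
        writer.writerow(_EVENT_HEADER)
        for ev in record.all_events_sorted():
            if isinstance(ev, DurationEvent):
                writer.writerow([ev.tag, "duration", repr(ev.start), repr(ev.end)])
            else:
                writer.writerow([ev.tag, "frequency", repr(ev.t), ""])
    return p


def read_exported_csv(path: str | Path) -> tuple[dict, list]:
    """Read back an exported CSV: (info dict, event list).

    Events come back as ``(tag, kind, start, end)`` tuples with ``end``
    ``None`` for frequency events — enough to recover the event multiset.
    """
    p = Path(path)
    if not p.is_file():
        raise StorageError(f"CSV file not found: {p}")
    info: dict[str, str] = {}
    events: list[tuple] = []
    with open(p, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        in_events = False
        for row in reader:
            if not row or all(not c for c in row):
                continue
            if tuple(row[:4]) == _EVENT_HEADER:
                in_events = True
                continue
            if not in_events:
                info[row[0]] = row[1] if len(row) > 1 else ""
            else:
                tag, kind, start, end = row[0], row[1], row[2], row[3]
                events.append(
                    (tag, kind, float(start), float(end) if end else None)
                )
    return info, events


# ---------------------------------------------------------------------------
# "Analyze Sessions": per-session keystroke bins into the KSF workbook
# ---------------------------------------------------------------------------

def _session_bins(record: SessionRecord) -> dict[str, float]:
    bins: dict[str, float] = {}
    for b in record.schema.bindings:
        if b.kind == "frequency":
            bins[b.behavior] = float(
                sum(1 for e in record.freq_events if e.tag == b.behavior)
            )
        else:
            bins[b.behavior] = float(
                sum(e.length for e in record.dur_events if e.tag == b.behavior)
            )
    return bins


def analyze_sessions_to_ksf(
    layout: ProjectLayout,
    ksf_path: str | Path,
    include_reliability: bool = False,
) -> Path:
    """Populate a per-session results sheet in (or as) a KSF workbook.

    Row *k* of the ``Sessions`` sheet holds session *k*'s per-key totals —
    event count for frequency keys, total episode seconds for duration
    keys — starting from session 1.  A session number that was never run
    leaves a blank row (distinguishing "not run" from "no responding").
    Sessions with non-integer numbers are appended after, in save order,
    flagged in a final column.
    """
    saved = iter_saved_sessions(layout, include_reliability=include_reliability)
    if not saved:
        raise StorageError(f"no saved sessions found under {layout.raw_dir}")

    integer_sessions: dict[int, SessionRecord] = {}
    other_sessions: list[SessionRecord] = []
    behaviors: list[str] = []
    for _, rec in saved:
        for tag in rec.schema.behaviors():
            if tag not in behaviors:
                behaviors.append(tag)
        try:
            integer_sessions[int(rec.info.session_number)] = rec
        except ValueError:
            other_sessions.append(rec)

    p = Path(ksf_path)
    if p.is_file():
        wb = openpyxl.load_workbook(p)
        if ANALYSIS_SHEET in wb.sheetnames:
            del wb[ANALYSIS_SHEET]
        ws = wb.create_sheet(ANALYSIS_SHEET)
    else:
        wb = openpyxl.Workbook()
        ws = wb.active
        ws.title = ANALYSIS_SHEET

    ws.append(["Session"] + behaviors + ["Flag"])
    if integer_sessions:
        for k in range(1, max(integer_sessions) + 1):
            rec = integer_sessions.get(k)
            if rec is None:
                ws.append([k])  # blank row: session not run
            else:
                bins = _session_bins(rec)
                ws.append([k] + [bins.get(tag) for tag in behaviors] + [None])
    for rec in other_sessions:
        bins = _session_bins(rec)
        ws.append(
            [rec.info.session_number]
            + [bins.get(tag) for tag in behaviors]
            + ["non-integer session number"]
        )
    wb.save(p)
    return p
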