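"""Keystroke files (KSFs): the spreadsheets binding keys to target behaviors.

A KSF is a small XLSX workbook with two sheets:

* ``Keys`` — columns ``Key``, ``Behavior``, ``Type`` (``Frequency`` or
  ``Duration``), one row per binding.  Columns are matched by header, not
  position, so reordered templates load fine.
* ``Conditions`` — one experimental-condition label per row in column A
  (e.g. baseline, treatment, tangible, toy play).  Optional.

A frequency key scores one discrete instance of a behavior per press; a
duration key opens a timed episode on one press and closes it on the next.
Keys are case-sensitive, since keystroke capture distinguishes case.

Regenerating a revision of a KSF writes a fresh workbook containing only
these two sheets — any extra sheets, charts or cell formulas in the source
workbook are deliberately not carried over.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import openpyxl

from .errors import SchemaError

#: Control keys claimed by the recorder; they can never be bound to a behavior.
RESERVED_KEYS = frozenset({"Esc", "LeftCtrl", "RightCtrl", "Backspace",
                           "ESC", "LCTRL", "RCTRL", "BKSP"})

KEYS_SHEET = "Keys"
CONDITIONS_SHEET = "Conditions"

BindingKind = Literal["frequency", "duration"]


@dataclass(frozen=True)
class KeyBinding:
    """One key → behavior correspondence."""

    key: str
    behavior: str
    kind: BindingKind

    def __post_init__(self) -> None:
        if self.key in RESERVED_KEYS:
            raise SchemaError(f"key {self.key!r} is reserved for session control")
        if len(self.key) != 1 or not self.key.isprintable() or self.key.isspace():
            raise SchemaError(
                f"key {self.key!r} must be exactly one printable character"
            )
        if not self.behavior or not self.behavior.strip():
            raise SchemaError(f"binding for key {self.key!r} has an empty behavior label")
        if self.kind not in ("frequency", "duration"):
            raise SchemaError(f"unknown binding kind {self.kind!r}")


@dataclass(frozen=True)
class KeystrokeSchema:
    """A named, ordered set of key bindings plus the experiment's conditions."""

    name: str
    bindings: tuple[KeyBinding, ...] = ()
    conditions: tuple[str, ...] = ()
    revision: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bindings", tuple(self.bindings))
        object.__setattr__(self, "conditions", tuple(str(c) for c in self.conditions))
        self.validate()

    def validate(self) -> None:
        seen_keys: set[str] = set()
        seen_behaviors: set[str] = set()
        for b in self.bindings:
            if b.key in seen_keys:
                raise SchemaError(f"duplicate key {b.key!r} in schema {self.name!r}")
            if b.behavior in seen_behaviors:
                raise SchemaError(
                    f"duplicate behavior label {b.behavior!r} in schema {self.name!r}"
                )
            seen_keys.add(b.key)
            seen_behaviors.add(b.behavior)
        if self.revision < 0:
            raise SchemaError("revision must be non-negative")

    # -- lookups ---------------------------------------------------------

    @property
    def frequency_bindings(self) -> tuple[KeyBinding, ...]:
        return tuple(b for b in self.bindings if b.kind == "frequency")

    @property
    def duration_bindings(self) -> tuple[KeyBinding, ...]:
        return tuple(b for b in self.bindings if b.kind == "duration")

    def binding_for_key(self, key: str) -> KeyBinding | None:
        for b in self.bindings:
            if b.key == key:
                return b
        return None

    def behaviors(self) -> tuple[str, ...]:
        return tuple(b.behavior for b in self.bindings)

    def has_behavior(self, tag: str) -> bool:
        return any(b.behavior == tag for b in self.bindings)

    def kind_of(self, tag: str) -> BindingKind:
        for b in self.bindings:
            if b.behavior == tag:
                return b.kind
        raise SchemaError(f"behavior {tag!r} not bound in schema {self.name!r}")

    # -- (de)serialization helpers used by session JSON ------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "revision": self.revision,
            "bindings": [
                {"key": b.key, "behavior": b.behavior, "kind": b.kind}
                for b in self.bindings
            ],
            "conditions": list(self.conditions),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KeystrokeSchema":
        try:
            bindings = tuple(
                KeyBinding(b["key"], b["behavior"], b["kind"]) for b in d["bindings"]
            )
            return cls(
                name=d["name"],
                bindings=bindings,
                conditions=tuple(d.get("conditions", ())),
                revision=int(d.get("revision", 0)),
            )
        except KeyError as exc:
            raise SchemaError(f"schema dictionary missing field {exc.args[0]!r}") from exc


# ---------------------------------------------------------------------------
# Workbook I/O
# ---------------------------------------------------------------------------

_KIND_TO_SHEET = {"frequency": "Frequency", "duration": "Duration"}
_SHEET_TO_KIND = {v.lower(): k for k, v in _KIND_TO_SHEET.items()}


def load_schema(workbook_path: str | Path) -> KeystrokeSchema:
    """Read and validate a KSF workbook.

    The schema name is the workbook's file stem, with any ``_rev<k>`` suffix
    stripped into the revision number.

    Raises :class:`SchemaError` on a missing file, a missing ``Keys`` sheet,
    duplicate keys, or empty behavior labels.
    """
    path = Path(workbook_path)
    if not path.is_file():
        raise SchemaError(f"KSF workbook not found: {path}")
    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    try:
        if KEYS_SHEET not in wb.sheetnames:
            raise SchemaError(f"workbook {path.name} has no {KEYS_SHEET!r} sheet")
        ws = wb[KEYS_SHEET]
        rows = list(ws.iter_rows(values_only=True))
        if not rows:
            raise SchemaError(f"{KEYS_SHEET!r} sheet of {path.name} is empty")
        header = [str(c).strip().lower() if c is not None else "" for c in rows[0]]
        try:
            i_key = header.index("key")
            i_beh = header.index("behavior")
            i_kind = header.index("type")
        except ValueError as exc:
            raise SchemaError(
                f"{KEYS_SHEET!r} sheet must have Key, Behavior and Type columns; "
                f"got {rows[0]!r}"
            ) from exc
        bindings = []
        for row in rows[1:]:
            if row is None or all(c is None for c in row):
                continue
            key = row[i_key]
            behavior = row[i_beh]
            kind_cell = row[i_kind]
            if key is None or behavior is None or not str(behavior).strip():
                raise SchemaError(
                    f"row {row!r} of {path.name} has an empty key or behavior label"
                )
            kind = _SHEET_TO_KIND.get(str(kind_cell).strip().lower())
            if kind is None:
                raise SchemaError(
                    f"unknown binding type {kind_cell!r} for key {key!r}; "
                    "expected Frequency or Duration"
                )
            bindings.append(KeyBinding(str(key), str(behavior), kind))

        conditions: list[str] = []
        if CONDITIONS_SHEET in wb.sheetnames:
            for row in wb[CONDITIONS_SHEET].iter_rows(values_only=True):
                if row and row[0] is not None and str(row[0]).strip():
                    conditions.append(str(row[0]))
    finally:
        wb.close()

    name, revision = _split_revision(path.stem)
    return KeystrokeSchema(
        name=name,
        bindings=tuple(bindings),
        conditions=tuple(conditions),
        revision=revision,
    )


def add_binding(
    schema: KeystrokeSchema, key: str, behavior: str, kind: BindingKind
) -> KeystrokeSchema:
    """Return a new schema with the binding appended; the input is unmodified."""
    new = KeyBinding(key, behavior, kind)
    return replace(schema, bindings=schema.bindings + (new,))


_REV_RE = re.compile(r"^(?P<name>.*)_rev(?P<rev>\d+)$")


def _split_revision(stem: str) -> tuple[str, int]:
    m = _REV_RE.match(stem)
    if m:
        return m.group("name"), int(m.group("rev"))
    return stem, 0


def generate_revision(schema: KeystrokeSchema, ksf_dir: str | Path) -> Path:
    """Write a fresh revision of the schema into *ksf_dir*.

    The output workbook carries exactly the ``Keys`` and ``Conditions``
    sheets — formatting, formulas and extra sheets of any source workbook are
    dropped.  The filename is ``<name>_rev<k>.xlsx`` with ``k`` one above the
    highest revision already present in the directory (and at least
    ``schema.revision + 1``), so successive revisions sort and never collide.
    """
    out_dir = Path(ksf_dir)
    if not out_dir.is_dir():
        raise SchemaError(f"KSF directory does not exist: {out_dir}")

    existing = 0
    for p in out_dir.glob(f"{schema.name}_rev*.xlsx"):
        _, rev = _split_revision(p.stem)
        existing = max(existing, rev)
    next_rev = max(existing, schema.revision) + 1

    wb = openpyxl.Workbook()
    ws = wb.active
    ws.title = KEYS_SHEET
    ws.append(["Key", "Behavior", "Type"])
    for b in schema.bindings:
        ws.append([b.key, b.behavior, _KIND_TO_SHEET[b.kind]])
    cond = wb.create_sheet(CONDITIONS_SHEET)
    for label in schema.conditions:
        cond.append([label])

    out_path = out_dir / f"{schema.name}_rev{next_rev}.xlsx"
    try:
        wb.save(out_path)
    except OSError as exc:
        raise SchemaError(f"cannot write KSF revision to {out_path}: {exc}") from exc
    return out_path
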