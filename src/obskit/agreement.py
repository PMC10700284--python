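"""Interobserver agreement (IOA) between a primary and a reliability session.

Events are binned into half-open windows ``[k·w, (k+1)·w)`` of a
configurable size *w*; the final window may be partial and is included in
every denominator.  Three standard behavior-analytic coefficients are
reported side by side for each frequency key:

* **total-count IOA** — ``100 · min(P, R) / max(P, R)`` over session
  totals;
* **exact count-per-interval IOA** — the percentage of windows in which
  the two observers' counts agree exactly;
* **block-by-block (mean count-per-interval) IOA** — the mean over
  windows of ``min/max`` of the per-window counts.

Duration keys are scored on per-window overlap seconds: total-count IOA
over total seconds and a block-by-block coefficient over per-window
seconds (an exact count match is not meaningful for continuous overlap,
so no exact coefficient is reported for duration keys).

The ``0/0`` window — neither observer scored anything — counts as perfect
agreement (the conventional choice).  Note this inflates agreement for
rare behaviors; interpret high coefficients on near-empty records with
care.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import openpyxl

from .errors import AgreementError
from .session import DurationEvent, SessionRecord

REPORT_TABS = ("Primary", "Reliability", "Agreement")


@dataclass(frozen=True)
class WindowedCounts:
    """Per-window event counts (frequency keys) or overlap seconds (duration)."""

    key: str
    window_s: float
    counts: np.ndarray
    kind: str = "frequency"

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))

    @property
    def n_windows(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def n_windows_for(duration_s: float, window_s: float) -> int:
    """Number of windows covering a session: ``ceil(duration / window)``."""
    if window_s <= 0:
        raise AgreementError(f"window size must be positive, got {window_s}")
    return max(1, int(math.ceil(duration_s / window_s - 1e-9)))


def bin_events(
    record: SessionRecord, key: str, window_s: float,
    duration_s: Optional[float] = None,
) -> WindowedCounts:
    """Bin one key's events into windows of *window_s* seconds.

    Frequency events are counted into the half-open window containing
    their time; an event at exactly ``t = k·w`` belongs to window ``k``.
    Duration events contribute their overlap seconds to every window they
    intersect.  An event exactly at the session's end lands in the final
    (possibly partial) window.
    """
    if window_s <= 0:
        raise AgreementError(f"window size must be positive, got {window_s}")
    if not record.schema.has_behavior(key):
        raise AgreementError(f"key {key!r} not present in the session schema")
    duration = record.info.duration if duration_s is None else duration_s
    n = n_windows_for(duration, window_s)
    kind = record.schema.kind_of(key)
    counts = np.zeros(n)
    if kind == "frequency":
        for ev in record.freq_events:
            if ev.tag != key:
                continue
            idx = min(int(math.floor(ev.t / window_s)), n - 1)
            counts[idx] += 1
    else:
        edges_lo = np.arange(n) * window_s
        edges_hi = np.minimum(edges_lo + window_s, max(duration, window_s * n))
        for ev in record.dur_events:
            if ev.tag != key:
                continue
            overlap = np.minimum(edges_hi, ev.end) - np.maximum(edges_lo, ev.start)
            counts += np.clip(overlap, 0.0, None)
    return WindowedCounts(key=key, window_s=window_s, counts=counts, kind=kind)


# ---------------------------------------------------------------------------
# Coefficients
# ---------------------------------------------------------------------------

def total_count_ioa(p_total: float, r_total: float) -> float:
    """Total-count IOA: ``100 · min/max``, defined as 100 when both are 0."""
    if p_total < 0 or r_total < 0:
        raise AgreementError("event counts cannot be negative")
    if p_total == 0 and r_total == 0:
        return 100.0
    return 100.0 * min(p_total, r_total) / max(p_total, r_total)


def _pad_to_match(p: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if p.size == r.size:
        return p, r
    warnings.warn(
        f"window counts differ ({p.size} vs {r.size}); padding the shorter "
        "with zeros", stacklevel=3,
    )
    n = max(p.size, r.size)
    return (
        np.pad(p, (0, n - p.size)),
        np.pad(r, (0, n - r.size)),
    )


def _per_window_ratio(p: np.ndarray, r: np.ndarray) -> np.ndarray:
    lo = np.minimum(p, r)
    hi = np.maximum(p, r)
    ratio = np.ones_like(hi, dtype=float)  # 0/0 window -> perfect agreement
    nz = hi > 0
    ratio[nz] = lo[nz] / hi[nz]
    return ratio


def windowed_agreement(p: WindowedCounts, r: WindowedCounts) -> dict[str, float]:
    """Exact count-per-interval and block-by-block IOA for frequency counts."""
    if p.key != r.key:
        raise AgreementError(f"cannot compare different keys {p.key!r} and {r.key!r}")
    if p.window_s != r.window_s:
        raise AgreementError("window sizes differ between observers")
    pc, rc = _pad_to_match(p.counts, r.counts)
    exact = 100.0 * float(np.mean(pc == rc))
    block = 100.0 * float(np.mean(_per_window_ratio(pc, rc)))
    return {"exact_ioa_pct": exact, "block_ioa_pct": block}


def duration_agreement(p: WindowedCounts, r: WindowedCounts) -> dict[str, float]:
    """Block-by-block IOA over per-window overlap seconds for duration keys."""
    if p.key != r.key:
        raise AgreementError(f"cannot compare different keys {p.key!r} and {r.key!r}")
    if p.window_s != r.window_s:
        raise AgreementError("window sizes differ between observers")
    pc, rc = _pad_to_match(p.counts, r.counts)
    return {"block_ioa_pct": 100.0 * float(np.mean(_per_window_ratio(pc, rc)))}


@dataclass(frozen=True)
class KeyAgreement:
    key: str
    kind: str
    total_ioa_pct: float
    block_ioa_pct: float
    exact_ioa_pct: Optional[float]  # frequency keys only


@dataclass(frozen=True)
class AgreementReport:
    window_s: float
    per_key: dict[str, KeyAgreement]
    primary_counts: dict[str, WindowedCounts]
    reliability_counts: dict[str, WindowedCounts]


def compute_agreement(
    primary: SessionRecord, reliability: SessionRecord, window_s: float
) -> AgreementReport:
    """Compute all coefficients for every behavior shared by both schemas.

    Both sessions must carry the same key set; differing durations are
    resolved by windowing over the longer one (the shorter record pads
    with empty windows), with a warning.
    """
    p_tags = set(primary.schema.behaviors())
    r_tags = set(reliability.schema.behaviors())
    if p_tags != r_tags:
        only_p = sorted(p_tags - r_tags)
        only_r = sorted(r_tags - p_tags)
        raise AgreementError(
            "session schemas disagree: behaviors only in primary "
            f"{only_p}, only in reliability {only_r}"
        )
    d_p, d_r = primary.info.duration, reliability.info.duration
    duration = max(d_p, d_r)
    if d_p != d_r:
        warnings.warn(
            f"session durations differ ({d_p} vs {d_r} s); using the longer",
            stacklevel=2,
        )
    per_key: dict[str, KeyAgreement] = {}
    p_counts: dict[str, WindowedCounts] = {}
    r_counts: dict[str, WindowedCounts] = {}
    for binding in primary.schema.bindings:
        tag = binding.behavior
        pw = bin_events(primary, tag, window_s, duration_s=duration)
        rw = bin_events(reliability, tag, window_s, duration_s=duration)
        p_counts[tag] = pw
        r_counts[tag] = rw
        total = total_count_ioa(pw.total, rw.total)
        if binding.kind == "frequency":
            wa = windowed_agreement(pw, rw)
            per_key[tag] = KeyAgreement(
                key=tag, kind="frequency", total_ioa_pct=total,
                block_ioa_pct=wa["block_ioa_pct"],
                exact_ioa_pct=wa["exact_ioa_pct"],
            )
        else:
            da = duration_agreement(pw, rw)
            per_key[tag] = KeyAgreement(
                key=tag, kind="duration", total_ioa_pct=total,
                block_ioa_pct=da["block_ioa_pct"], exact_ioa_pct=None,
            )
    return AgreementReport(
        window_s=window_s, per_key=per_key,
        primary_counts=p_counts, reliability_counts=r_counts,
    )


# ---------------------------------------------------------------------------
# Report workbook
# ---------------------------------------------------------------------------

def _write_raw_tab(ws, record: SessionRecord) -> None:
    ws.append(["Tag", "Kind", "Start (s)", "End (s)"])
    for ev in record.all_events_sorted():
        if isinstance(ev, DurationEvent):
            ws.append([ev.tag, "duration", ev.start, ev.end])
        else:
            ws.append([ev.tag, "frequency", ev.t, None])


def build_agreement_report(
    primary: SessionRecord,
    reliability: SessionRecord,
    window_s: float,
    out_path: str | Path,
) -> Path:
    """Write the three-tab agreement workbook and return its path.

    Tabs: ``Primary`` (raw events), ``Reliability`` (raw events), and
    ``Agreement`` (coefficients per key at the given window size, plus the
    per-window count vectors).
    """
    report = compute_agreement(primary, reliability, window_s)
    wb = openpyxl.Workbook()
    ws_p = wb.active
    ws_p.title = "Primary"
    _write_raw_tab(ws_p, primary)
    _write_raw_tab(wb.create_sheet("Reliability"), reliability)

    ws = wb.create_sheet("Agreement")
    ws.append(["Window size (s)", window_s])
    ws.append([])
    ws.append(["Key", "Kind", "Total IOA (%)", "Exact IOA (%)", "Block IOA (%)"])
    for tag, ka in report.per_key.items():
        ws.append([tag, ka.kind, ka.total_ioa_pct, ka.exact_ioa_pct, ka.block_ioa_pct])
    ws.append([])
    ws.append(["Per-window counts (primary | reliability)"])
    for tag in report.per_key:
        pw = report.primary_counts[tag]
        rw = report.reliability_counts[tag]
        ws.append([tag, "P"] + [float(c) for c in pw.counts])
        ws.append([tag, "R"] + [float(c) for c in rw.counts])

    p = Path(out_path)
    wb.save(p)
    return p
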