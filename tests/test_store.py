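"""Project directory tree, recent-projects config, saving, CSV export."""

import json
from dataclasses import replace

import openpyxl
import pytest

from obskit import (
    RECENT_PROJECTS_CAPACITY,
    RecentProjects,
    StorageError,
    analyze_sessions_to_ksf,
    default_info,
    export_csv,
    init_phase_dirs,
    load_config,
    read_exported_csv,
    save_config,
    save_session,
    update_recent_projects,
)
from obskit.session import DurationEvent, FrequencyEvent, SessionRecord


class TestInitPhaseDirs:
    def test_creates_standard_subfolders(self, tmp_path):
        layout = init_phase_dirs(tmp_path, "Proj", "Patient", "Self-injury",
                                 "Assessment", mrn="12345")
        phase = tmp_path / "Proj" / "Patient" / "Self-injury Assessment"
        assert layout.phase_dir == phase
        for sub in ("Export", "Graph", "KSF", "Raw Data"):
            assert (phase / sub).is_dir()
        for sub in ("Primary", "Reliability"):
            assert (phase / "Raw Data" / sub).is_dir()

    def test_idempotent(self, tmp_path):
        a = init_phase_dirs(tmp_path, "P", "Pt", "C", "Assessment")
        b = init_phase_dirs(tmp_path, "P", "Pt", "C", "Assessment")
        assert a == b

    def test_patient_registry_accumulates_concerns(self, tmp_path):
        init_phase_dirs(tmp_path, "P", "Pt", "Aggression", "Assessment",
                        mrn="0042")
        layout = init_phase_dirs(tmp_path, "P", "Pt", "Elopement", "Treatment")
        registry = json.loads((layout.patient_dir / "patient.json").read_text())
        assert registry["mrn"] == "0042"
        assert registry["concerns"] == ["Aggression", "Elopement"]

    def test_empty_names_rejected(self, tmp_path):
        with pytest.raises(StorageError, match="non-empty"):
            init_phase_dirs(tmp_path, "", "Pt", "C", "Assessment")


class TestRecentProjects:
    def test_capacity_20_drops_oldest(self):
        state = RecentProjects()
        for i in range(25):
            state = update_recent_projects(state, f"/projects/p{i:02d}")
        assert len(state) == RECENT_PROJECTS_CAPACITY == 20
        assert state.paths[0] == "/projects/p24"
        for i in range(5):
            assert f"/projects/p{i:02d}" not in state.paths

    def test_reinsert_moves_to_front(self):
        state = RecentProjects(("a", "b", "c"))
        out = update_recent_projects(state, "c")
        assert out.paths == ("c", "a", "b")

    def test_insert_into_empty(self):
        assert update_recent_projects(RecentProjects(), "x").paths == ("x",)

    def test_config_round_trip(self, tmp_path):
        state = RecentProjects(("a", "b"))
        path = save_config(state, tmp_path / "config.json")
        assert load_config(path) == state

    def test_missing_config_is_empty(self, tmp_path):
        assert load_config(tmp_path / "nope.json") == RecentProjects()


class TestSaveSession:
    def test_primary_and_reliability_locations(self, tmp_path, session):
        layout = init_phase_dirs(tmp_path, "P", "Pt", "Self-injury", "Assessment")
        p_path = save_session(session, layout)
        assert p_path.parent == layout.raw_subdir(False)
        rel = replace(session, info=replace(session.info, is_reliability=True))
        r_path = save_session(rel, layout)
        assert r_path.parent == layout.raw_subdir(True)
        assert r_path.stem.endswith("_R")

    def test_collision_raises_unless_forced(self, tmp_path, session):
        layout = init_phase_dirs(tmp_path, "P", "Pt", "Self-injury", "Assessment")
        save_session(session, layout)
        with pytest.raises(StorageError, match="already exists"):
            save_session(session, layout)
        save_session(session, layout, force=True)  # explicit replace allowed

    def test_uninitialized_layout_rejected(self, tmp_path, session):
        from obskit.store import ProjectLayout

        layout = ProjectLayout(tmp_path, "P", "Pt", "C", "Assessment")
        with pytest.raises(StorageError, match="not initialized"):
            save_session(session, layout)


class TestExportCsv:
    def test_events_in_time_order(self, schema, tmp_path):
        rec = SessionRecord(
            info=default_info(schema, 20.0),
            freq_events=(FrequencyEvent("hitting", 1.0),
                         FrequencyEvent("hitting", 3.0),
                         FrequencyEvent("hitting", 5.0)),
            schema=schema,
        )
        _, events = read_exported_csv(export_csv(rec, tmp_path / "s.csv"))
        assert [e[2] for e in events] == [1.0, 3.0, 5.0]

    def test_empty_record_has_info_and_header_only(self, empty_session, tmp_path):
        info, events = read_exported_csv(
            export_csv(empty_session, tmp_path / "e.csv"))
        assert events == []
        assert info["assessment"] == "Functional Analysis"

    def test_every_info_field_appears_once(self, session, tmp_path):
        path = export_csv(session, tmp_path / "s.csv")
        lines = path.read_text().splitlines()
        header_idx = next(i for i, l in enumerate(lines) if l.startswith("Tag,"))
        keys = [l.split(",")[0] for l in lines[:header_idx] if l.strip(", ")]
        assert len(keys) == len(set(keys)) == 12

    def test_round_trip_recovers_event_multiset(self, session, tmp_path):
        _, events = read_exported_csv(export_csv(session, tmp_path / "s.csv"))
        expected = sorted(
            [("f", e.tag, e.t, None) for e in session.freq_events]
            + [("d", e.tag, e.start, e.end) for e in session.dur_events])
        got = sorted(
            [("f" if kind == "frequency" else "d", tag, start, end)
             for tag, kind, start, end in events])
        assert got == expected


class TestAnalyzeSessions:
    def _save(self, layout, schema, number, freq_times=(), dur_spans=()):
        info = default_info(schema, 60.0, session_number=number)
        rec = SessionRecord(
            info=info,
            freq_events=tuple(FrequencyEvent("hitting", t)
                              for t in sorted(freq_times)),
            dur_events=tuple(DurationEvent("aggression", a, b)
                             for a, b in sorted(dur_spans)),
            schema=schema,
        )
        save_session(rec, layout)

    def test_rows_hold_per_session_bins(self, tmp_path, schema):
        layout = init_phase_dirs(tmp_path, "P", "Pt", "C", "Assessment")
        self._save(layout, schema, "1", freq_times=[1.0, 2.0, 3.0])
        self._save(layout, schema, "2", freq_times=[5.0],
                   dur_spans=[(10.0, 22.0)])
        out = analyze_sessions_to_ksf(layout, tmp_path / "results.xlsx")
        ws = openpyxl.load_workbook(out)["Sessions"]
        rows = list(ws.iter_rows(values_only=True))
        header = rows[0]
        col = {name: i for i, name in enumerate(header)}
        assert rows[1][col["hitting"]] == 3.0
        assert rows[2][col["hitting"]] == 1.0
        assert rows[2][col["aggression"]] == pytest.approx(12.0)

    def test_gap_sessions_left_blank(self, tmp_path, schema):
        layout = init_phase_dirs(tmp_path, "P", "Pt", "C", "Assessment")
        self._save(layout, schema, "1", freq_times=[1.0])
        self._save(layout, schema, "3", freq_times=[2.0])
        out = analyze_sessions_to_ksf(layout, tmp_path / "results.xlsx")
        ws = openpyxl.load_workbook(out)["Sessions"]
        rows = list(ws.iter_rows(values_only=True))
        assert rows[2][0] == 2
        assert all(c is None for c in rows[2][1:])  # not run, not zero

    def test_zero_event_session_filled_with_zeros(self, tmp_path, schema):
        layout = init_phase_dirs(tmp_path, "P", "Pt", "C", "Assessment")
        self._save(layout, schema, "1")
        out = analyze_sessions_to_ksf(layout, tmp_path / "results.xlsx")
        ws = openpyxl.load_workbook(out)["Sessions"]
        rows = list(ws.iter_rows(values_only=True))
        assert rows[1][1:4] == (0.0, 0.0, 0.0)

    def test_non_integer_sessions_appended_flagged(self, tmp_path, schema):
        layout = init_phase_dirs(tmp_path, "P", "Pt", "C", "Assessment")
        self._save(layout, schema, "1", freq_times=[1.0])
        self._save(layout, schema, "2023-03-05a", freq_times=[2.0])
        out = analyze_sessions_to_ksf(layout, tmp_path / "results.xlsx")
        ws = openpyxl.load_workbook(out)["Sessions"]
        rows = list(ws.iter_rows(values_only=True))
        assert rows[-1][0] == "2023-03-05a"
        assert rows[-1][-1] == "non-integer session number"

    def test_no_sessions_rejected(self, tmp_path):
        layout = init_phase_dirs(tmp_path, "P", "Pt", "C", "Assessment")
        with pytest.raises(StorageError, match="no saved sessions"):
            analyze_sessions_to_ksf(layout, tmp_path / "results.xlsx")
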