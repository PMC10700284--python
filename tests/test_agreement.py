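"""Windowed interobserver agreement: binning, coefficients, report workbook."""

import math

import numpy as np
import openpyxl
import pytest

from obskit import (
    AgreementError,
    DurationEvent,
    FrequencyEvent,
    ObserverErrorModel,
    SessionRecord,
    WindowedCounts,
    bin_events,
    build_agreement_report,
    compute_agreement,
    default_info,
    duration_agreement,
    gen_observer_pair,
    gen_session_record,
    total_count_ioa,
    windowed_agreement,
)


def _freq_session(schema, times, duration, tag="hitting"):
    events = tuple(FrequencyEvent(tag, t) for t in sorted(times))
    return SessionRecord(info=default_info(schema, duration),
                         freq_events=events, schema=schema)


def _dur_session(schema, spans, duration, tag="aggression"):
    events = tuple(DurationEvent(tag, a, b) for a, b in sorted(spans))
    return SessionRecord(info=default_info(schema, duration),
                         dur_events=events, schema=schema)


class TestBinEvents:
    def test_frequency_counts_per_window(self, schema):
        rec = _freq_session(schema, [1.0, 5.0, 12.0], 20.0)
        out = bin_events(rec, "hitting", 10.0)
        np.testing.assert_array_equal(out.counts, [2.0, 1.0])

    def test_empty_session_zero_windows(self, schema):
        rec = _freq_session(schema, [], 20.0)
        np.testing.assert_array_equal(bin_events(rec, "hitting", 10.0).counts,
                                      [0.0, 0.0])

    def test_duration_overlap_seconds(self, schema):
        rec = _dur_session(schema, [(0.0, 10.0)], 20.0)
        out = bin_events(rec, "aggression", 30.0)
        np.testing.assert_allclose(out.counts, [10.0])

    def test_duration_split_across_windows(self, schema):
        rec = _dur_session(schema, [(8.0, 13.0)], 20.0)
        out = bin_events(rec, "aggression", 10.0)
        np.testing.assert_allclose(out.counts, [2.0, 3.0])

    def test_boundary_event_belongs_to_upper_window(self, schema):
        rec = _freq_session(schema, [10.0], 20.0)
        np.testing.assert_array_equal(bin_events(rec, "hitting", 10.0).counts,
                                      [0.0, 1.0])

    def test_unknown_key_and_bad_window_rejected(self, schema):
        rec = _freq_session(schema, [1.0], 20.0)
        with pytest.raises(AgreementError, match="not present"):
            bin_events(rec, "levitating", 10.0)
        with pytest.raises(AgreementError, match="positive"):
            bin_events(rec, "hitting", 0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_binning_conserves_totals(self, schema, seed):
        rec = gen_session_record(
            schema, {"hitting": 0.3, "aggression": 0.05}, 100.0, seed)
        for window in (7.0, 10.0, 33.0):
            counts = bin_events(rec, "hitting", window)
            assert counts.total == len(rec.freq_events)
            dur_counts = bin_events(rec, "aggression", window)
            total_seconds = sum(e.length for e in rec.dur_events)
            assert dur_counts.total == pytest.approx(total_seconds)
        assert math.ceil(100.0 / 7.0) == bin_events(rec, "hitting", 7.0).n_windows


class TestCoefficients:
    @pytest.mark.parametrize("p, r, expected", [
        (4, 2, 50.0), (3, 3, 100.0), (0, 0, 100.0),
    ])
    def test_total_count(self, p, r, expected):
        assert total_count_ioa(p, r) == pytest.approx(expected)

    def test_total_count_rejects_negatives(self):
        with pytest.raises(AgreementError):
            total_count_ioa(-1, 2)

    def test_windowed_example(self):
        p = WindowedCounts("hitting", 10.0, [2, 1, 0])
        r = WindowedCounts("hitting", 10.0, [1, 1, 0])
        out = windowed_agreement(p, r)
        assert out["exact_ioa_pct"] == pytest.approx(200.0 / 3.0)
        assert out["block_ioa_pct"] == pytest.approx(100.0 * (0.5 + 1 + 1) / 3)

    def test_identical_vectors_are_perfect(self):
        p = WindowedCounts("hitting", 10.0, [3, 0, 2])
        assert windowed_agreement(p, p) == {"exact_ioa_pct": 100.0,
                                            "block_ioa_pct": 100.0}

    def test_all_zero_convention(self):
        p = WindowedCounts("hitting", 10.0, [0, 0])
        r = WindowedCounts("hitting", 10.0, [0, 0])
        assert windowed_agreement(p, r) == {"exact_ioa_pct": 100.0,
                                            "block_ioa_pct": 100.0}

    def test_mismatched_lengths_padded_with_warning(self):
        p = WindowedCounts("hitting", 10.0, [1, 1, 1])
        r = WindowedCounts("hitting", 10.0, [1, 1])
        with pytest.warns(UserWarning, match="padding"):
            out = windowed_agreement(p, r)
        assert out["exact_ioa_pct"] == pytest.approx(200.0 / 3.0)

    @pytest.mark.parametrize("p, r, expected", [
        ([10.0], [5.0], 50.0),
        ([4.0, 4.0], [4.0, 4.0], 100.0),
        ([0.0, 0.0], [0.0, 0.0], 100.0),
    ])
    def test_duration_block(self, p, r, expected):
        pw = WindowedCounts("aggression", 10.0, p, kind="duration")
        rw = WindowedCounts("aggression", 10.0, r, kind="duration")
        assert duration_agreement(pw, rw)["block_ioa_pct"] == pytest.approx(expected)

    def test_block_100_iff_all_windows_equal(self):
        p = WindowedCounts("hitting", 10.0, [2, 3, 0])
        r = WindowedCounts("hitting", 10.0, [2, 3, 1])
        out = windowed_agreement(p, r)
        assert out["block_ioa_pct"] < 100.0
        assert windowed_agreement(p, p)["block_ioa_pct"] == 100.0


def _naive_coefficients(p_counts, r_counts):
    """Per-window loop oracle, no vectorization."""
    n = max(len(p_counts), len(r_counts))
    p = list(p_counts) + [0.0] * (n - len(p_counts))
    r = list(r_counts) + [0.0] * (n - len(r_counts))
    exact = sum(1 for a, b in zip(p, r) if a == b) / n * 100.0
    ratios = []
    for a, b in zip(p, r):
        if a == b == 0:
            ratios.append(1.0)
        else:
            ratios.append(min(a, b) / max(a, b))
    return exact, 100.0 * sum(ratios) / n


@pytest.mark.parametrize("seed", range(12))
def test_vectorized_matches_naive_loop(schema, seed):
    base = gen_session_record(schema, {"hitting": 0.25, "kicking": 0.1,
                                       "aggression": 0.03}, 80.0, seed)
    model = ObserverErrorModel(drop_prob=0.3, add_rate=0.05,
                               jitter_sd=1.0, seed=seed + 100)
    primary, reliability = gen_observer_pair(base, model)
    report = compute_agreement(primary, reliability, 10.0)
    for tag, ka in report.per_key.items():
        p = report.primary_counts[tag].counts
        r = report.reliability_counts[tag].counts
        exact, block = _naive_coefficients(p, r)
        assert ka.block_ioa_pct == pytest.approx(block)
        if ka.kind == "frequency":
            assert ka.exact_ioa_pct == pytest.approx(exact)
        assert ka.total_ioa_pct == pytest.approx(
            total_count_ioa(float(np.sum(p)), float(np.sum(r))))


def test_symmetry_under_observer_swap(schema):
    base = gen_session_record(schema, {"hitting": 0.3, "aggression": 0.05},
                              100.0, 3)
    model = ObserverErrorModel(drop_prob=0.4, jitter_sd=2.0, seed=9)
    primary, reliability = gen_observer_pair(base, model)
    fwd = compute_agreement(primary, reliability, 10.0)
    rev = compute_agreement(reliability, primary, 10.0)
    for tag in fwd.per_key:
        assert fwd.per_key[tag].total_ioa_pct == pytest.approx(
            rev.per_key[tag].total_ioa_pct)
        assert fwd.per_key[tag].block_ioa_pct == pytest.approx(
            rev.per_key[tag].block_ioa_pct)


def test_schema_mismatch_lists_offending_keys(schema, schema_no_conditions):
    a = _freq_session(schema, [1.0], 20.0)
    b = SessionRecord(info=default_info(schema_no_conditions, 20.0),
                      schema=schema_no_conditions)
    with pytest.raises(AgreementError, match="kicking"):
        compute_agreement(a, b, 10.0)


def test_differing_durations_use_longer_with_warning(schema):
    a = _freq_session(schema, [1.0], 20.0)
    b = _freq_session(schema, [1.0], 40.0)
    with pytest.warns(UserWarning, match="durations differ"):
        report = compute_agreement(a, b, 10.0)
    assert report.primary_counts["hitting"].n_windows == 4


class TestReportWorkbook:
    def test_three_tabs_with_consistent_cells(self, schema, tmp_path):
        base = gen_session_record(schema, {"hitting": 0.3, "aggression": 0.05},
                                  60.0, 5)
        primary, reliability = gen_observer_pair(
            base, ObserverErrorModel(drop_prob=0.3, seed=6))
        out = build_agreement_report(primary, reliability, 10.0,
                                     tmp_path / "rep.xlsx")
        wb = openpyxl.load_workbook(out)
        assert wb.sheetnames == ["Primary", "Reliability", "Agreement"]
        report = compute_agreement(primary, reliability, 10.0)
        ws = wb["Agreement"]
        rows = {row[0]: row for row in ws.iter_rows(min_row=4, values_only=True)
                if row and row[0] in report.per_key
                and row[1] in ("frequency", "duration")}
        for tag, ka in report.per_key.items():
            assert rows[tag][2] == pytest.approx(ka.total_ioa_pct)
            assert rows[tag][4] == pytest.approx(ka.block_ioa_pct)

    def test_self_agreement_is_perfect(self, session, tmp_path):
        build_agreement_report(session, session, 10.0, tmp_path / "self.xlsx")
        report = compute_agreement(session, session, 10.0)
        for ka in report.per_key.values():
            assert ka.total_ioa_pct == 100.0
            assert ka.block_ioa_pct == 100.0
            if ka.exact_ioa_pct is not None:
                assert ka.exact_ioa_pct == 100.0

    def test_identity_error_model_gives_perfect_agreement(self, schema):
        base = gen_session_record(schema, {"hitting": 0.3}, 60.0, 8)
        primary, reliability = gen_observer_pair(base, ObserverErrorModel(seed=1))
        report = compute_agreement(primary, reliability, 10.0)
        assert all(ka.total_ioa_pct == 100.0 and ka.block_ioa_pct == 100.0
                   for ka in report.per_key.values())
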