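"""Unit and property tests for the FP-In reader/writer and label grammar."""

import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fluxqaqc.fp_format import (
    FPTable, TimestampCalendarError, TimestampFormatError, format_timestamp,
    infer_resolution, make_time_axis, parse_timestamp, parse_variable_name,
    read_fp_file, write_fp_file,
)
from fluxqaqc.registry import VariableRegistry


# ---------------------------------------------------------------------------
# timestamps
# ---------------------------------------------------------------------------

class TestTimestamps:
    def test_parse_basic(self):
        assert parse_timestamp("202001011130") == (2020, 1, 1, 11, 30)

    @pytest.mark.parametrize("bad", ["20200101113", "2020010111301", "20200101113a", ""])
    def test_malformed_token(self, bad):
        with pytest.raises(TimestampFormatError) as exc:
            parse_timestamp(bad)
        assert exc.value.token == bad

    @pytest.mark.parametrize("bad", ["202002300000", "202013010000", "202001012400",
                                     "202001010060", "202100290000"])
    def test_impossible_calendar_instant(self, bad):
        with pytest.raises(TimestampCalendarError):
            parse_timestamp(bad)

    def test_leap_day_valid(self):
        assert parse_timestamp("202002290000")[:3] == (2020, 2, 29)

    @settings(max_examples=500, deadline=None)
    @given(st.datetimes(min_value=datetime.datetime(1990, 1, 1),
                        max_value=datetime.datetime(2049, 12, 31)))
    def test_round_trip_against_calendar_oracle(self, dt):
        # the Python datetime module is the independent calendar oracle
        dt = dt.replace(second=0, microsecond=0)
        token = f"{dt.year:04d}{dt.month:02d}{dt.day:02d}{dt.hour:02d}{dt.minute:02d}"
        assert parse_timestamp(token) == (dt.year, dt.month, dt.day, dt.hour, dt.minute)
        assert format_timestamp(parse_timestamp(token)) == token


# ---------------------------------------------------------------------------
# variable-label grammar
# ---------------------------------------------------------------------------

class TestVariableGrammar:
    @pytest.mark.parametrize("label, base, pos, quals", [
        ("FC", "FC", None, ()),
        ("TA_1_1_1", "TA", (1, 1, 1), ()),
        ("SWC_2_3_1", "SWC", (2, 3, 1), ()),
        ("SW_IN", "SW_IN", None, ()),
        ("FC_PI_F", "FC", None, ("PI", "F")),
        ("TA_PI_F_1_1_1", "TA", (1, 1, 1), ("PI", "F")),
        ("LE_SD_2_1_1", "LE", (2, 1, 1), ("SD",)),
    ])
    def test_grammar(self, label, base, pos, quals):
        v = parse_variable_name(label)
        assert v.base == base
        assert v.general_qualifiers == quals
        if pos is None:
            assert not v.has_position
        else:
            assert (v.h_index, v.v_index, v.r_index) == pos
        assert v.label == label

    def test_partial_positional_triple_folds_into_base_with_warning(self):
        v = parse_variable_name("TA_1_1")
        assert v.base == "TA_1_1" and not v.has_position
        assert v.warnings

    def test_empty_label_rejected(self):
        with pytest.raises(ValueError):
            parse_variable_name("")

    def test_lower_case_warns(self):
        assert parse_variable_name("fc").warnings

    def test_positional_all_or_none_invariant(self):
        from fluxqaqc.fp_format import FPVariable
        with pytest.raises(ValueError):
            FPVariable(base="TA", h_index=1, v_index=1, r_index=None)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

class TestRegistry:
    def test_known_flux_entry(self):
        reg = VariableRegistry.default()
        fc = reg.lookup("FC")
        assert fc.kind == "flux" and "umolCO2" in fc.units

    def test_rh_is_percent_with_0_100_range(self):
        rh = VariableRegistry.default().lookup("RH")
        assert rh.is_percent and (rh.hard_min, rh.hard_max) == (0.0, 100.0)

    def test_unknown_base_is_a_value_not_an_error(self):
        assert VariableRegistry.default().lookup("ZZZ") is None

    def test_hard_limits_ordered_for_every_entry(self):
        for e in VariableRegistry.default():
            assert e.hard_min < e.hard_max

    def test_user_extensible(self):
        from fluxqaqc.registry import RegistryEntry
        reg = VariableRegistry.default()
        reg.add(RegistryEntry("NIRV", "nondimensional", -1, 1, "radiation"))
        assert reg.lookup("NIRV").units == "nondimensional"


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _small_table(n=3, resolution=30, cols=("FC", "TA")):
    start, end = make_time_axis("2020-06-01", n, resolution)
    data = pd.DataFrame({c: np.linspace(1.5, 2.5, n) + i
                         for i, c in enumerate(cols)})
    return FPTable(start, end, data, resolution, site_id="XX-Tst")


class TestFileIO:
    def test_conforming_file_no_diagnostics(self, tmp_path):
        p = tmp_path / "ok.csv"
        write_fp_file(_small_table(), p)
        table, diags = read_fp_file(p)
        assert len(table) == 3 and diags == []

    def test_nan_cell_mapped_to_missing_with_diagnostic(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("TIMESTAMP_START,TIMESTAMP_END,FC\n"
                     "202006010000,202006010030,NaN\n"
                     "202006010030,202006010100,2.5\n")
        table, diags = read_fp_file(p)
        assert np.isnan(table["FC"][0]) and table["FC"][1] == 2.5
        assert any(d.code == "NON_NUMERIC_CELL" for d in diags)

    def test_sentinel_variants_all_map_to_missing(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("TIMESTAMP_START,TIMESTAMP_END,FC\n"
                     "202006010000,202006010030,-9999\n"
                     "202006010030,202006010100,-9999.0\n"
                     "202006010030,202006010100,-9999.00\n")
        table, _ = read_fp_file(p)
        assert np.isnan(table["FC"]).all()

    def test_missing_written_exactly_as_sentinel(self, tmp_path):
        t = _small_table()
        t["FC"] = [1.0, np.nan, 3.0]
        p = tmp_path / "m.csv"
        write_fp_file(t, p)
        row = p.read_text().splitlines()[2]
        assert row.split(",")[2] == "-9999"

    def test_value_formatting_plain_decimal(self, tmp_path):
        t = _small_table(n=2, cols=("FC",))
        t["FC"] = [21.5, 0.001]
        p = tmp_path / "v.csv"
        write_fp_file(t, p)
        lines = p.read_text().splitlines()
        assert lines[1].split(",")[2] == "21.5"
        assert lines[2].split(",")[2] == "0.001"

    def test_round_trip_fixed_point(self, tmp_path):
        t = _small_table(n=10)
        t["FC"] = np.where(np.arange(10) % 3 == 0, np.nan, np.arange(10) * 1.1)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_fp_file(t, p1)
        t2, diags = read_fp_file(p1)
        assert diags == []
        write_fp_file(t2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert t.equals(t2)

    def test_refuses_to_write_nonconforming_table(self):
        t = _small_table()
        t.end = t.end + pd.Timedelta(minutes=30)
        with pytest.raises(ValueError):
            write_fp_file(t, "/dev/null")

    def test_semicolon_delimiter_diagnosed_and_parsed(self, tmp_path):
        p = tmp_path / "semi.csv"
        p.write_text("TIMESTAMP_START;TIMESTAMP_END;FC\n"
                     "202006010000;202006010030;1.5\n"
                     "202006010030;202006010100;2.0\n")
        table, diags = read_fp_file(p)
        assert any(d.code == "WRONG_DELIMITER" for d in diags)
        assert table["FC"][1] == 2.0

    def test_no_timestamp_columns_fatal(self, tmp_path):
        p = tmp_path / "nt.csv"
        p.write_text("A,B\n1,2\n")
        table, diags = read_fp_file(p)
        assert table is None
        assert any(d.fatal for d in diags)


class TestResolution:
    def test_half_hourly(self):
        start, _ = make_time_axis("2020-01-01", 5, 30)
        assert infer_resolution(start) == 30

    def test_modal_wins_over_gap(self):
        starts = pd.to_datetime(["2020-01-01 00:00", "2020-01-01 01:00",
                                 "2020-01-01 02:00", "2020-01-01 04:00",
                                 "2020-01-01 05:00"])
        assert infer_resolution(starts) == 60

    def test_unsupported_step_rejected(self):
        starts = pd.to_datetime(["2020-01-01 00:00", "2020-01-01 00:15",
                                 "2020-01-01 00:30"])
        with pytest.raises(ValueError):
            infer_resolution(starts)

    @settings(max_examples=50, deadline=None)
    @given(st.permutations(list(range(8))))
    def test_gap_order_invariance(self, perm):
        # resolution depends only on the multiset of steps
        steps = [30, 30, 30, 60, 30, 90, 30, 30]
        base = pd.Timestamp("2020-01-01")
        t1 = [base]
        for s in steps:
            t1.append(t1[-1] + pd.Timedelta(minutes=s))
        t2 = [base]
        for s in (steps[i] for i in perm):
            t2.append(t2[-1] + pd.Timedelta(minutes=s))
        assert infer_resolution(pd.DatetimeIndex(t1)) == \
            infer_resolution(pd.DatetimeIndex(t2))
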