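"""Unit tests for the six data checks: targeted fault recovery on single
seeds, padding invariance, and record-combination semantics.

The broad sensitivity/false-alarm statistics over many seeds live in the
acceptance suite; these tests pin down each detector's behavior and the
exactness contracts (lag recovery, u* bin recovery, breakpoint location).
"""

import numpy as np
import pandas as pd
import pytest

from fluxqaqc.config import QCConfig
from fluxqaqc.data_qaqc import (
    combine_with_prior, diurnal_composite, diurnal_seasonal_check,
    multivariate_check, physical_range_check, radiation_issue_check,
    run_data_qaqc, timestamp_alignment, ustar_filtering_check,
    variability_check, variable_coverage_check,
)
from fluxqaqc.fp_format import FPTable, make_time_axis
from fluxqaqc.reporting import Severity
from fluxqaqc.synthetic import (
    FaultSpec, SyntheticSiteConfig, generate_clean, inject_fault, make_fixture,
)


def codes(findings):
    return {f.code for f in findings}


class TestTimestampAlignment:
    @pytest.mark.parametrize("shift", [-4, -2, 2, 4])
    def test_injected_shift_recovered_exactly(self, clean_table, site, shift):
        t = inject_fault(clean_table, FaultSpec("TIMESTAMP_SHIFT", magnitude=shift))
        prof, findings = timestamp_alignment(t, site, QCConfig())
        lags = prof.lags[prof.valid]
        assert (lags == shift).mean() > 0.95
        assert prof.modal_lag() == shift
        assert "TIMESTAMP_SHIFT" in codes(findings)

    def test_clean_year_all_zero_lag(self, clean_table, site):
        prof, findings = timestamp_alignment(clean_table, site, QCConfig())
        assert prof.modal_lag() == 0
        assert findings == []

    def test_dst_two_plateau_signature(self, clean_table, site):
        t = inject_fault(clean_table, FaultSpec(
            "DST", span=("202003080200", "202011010200")))
        prof, findings = timestamp_alignment(t, site, QCConfig())
        assert "DST" in codes(findings)
        lags = set(prof.lags[prof.valid].tolist())
        assert {0, 2} <= lags

    def test_one_interval_lag_reads_as_begin_end_confusion(self, clean_table, site):
        t = inject_fault(clean_table, FaultSpec("TIMESTAMP_SHIFT", magnitude=1))
        _, findings = timestamp_alignment(t, site, QCConfig())
        assert "BEGIN_END_CONFUSION" in codes(findings)

    def test_desynchronized_streams(self, clean_table, site):
        t = clean_table.copy()
        t["PPFD_IN"] = np.roll(t["PPFD_IN"], 2)  # shift only one stream
        _, findings = timestamp_alignment(t, site, QCConfig())
        assert "NOT_SYNCHRONIZED" in codes(findings)

    def test_skipped_without_radiation(self, clean_table, site):
        t = clean_table.copy()
        t.data = t.data.drop(columns=["SW_IN", "PPFD_IN"])
        prof, findings = timestamp_alignment(t, site, QCConfig())
        assert prof is None
        assert codes(findings) == {"SKIPPED"}


class TestRadiationIssues:
    def test_clean_silent(self, clean_table, site):
        assert radiation_issue_check(clean_table, site, QCConfig()) == []

    def test_doubled_radiation_flags_ceiling(self, clean_table, site):
        t = inject_fault(clean_table, FaultSpec("UNIT_RATIO", var="SW_IN",
                                                magnitude=2.0))
        findings = radiation_issue_check(t, site, QCConfig())
        f = next(f for f in findings if f.code == "HIGH_RADIATION")
        assert f.metrics["fraction_above_ceiling"] > 0.5

    def test_am_pm_asymmetry_flags_tilt(self, clean_table, site):
        t = clean_table.copy()
        hour = t.start.hour.to_numpy()
        sw = t["SW_IN"].copy()
        sw[hour < 12] *= 1.15
        sw[hour >= 12] *= 0.85
        t["SW_IN"] = sw
        assert "TILTED" in codes(radiation_issue_check(t, site, QCConfig()))

    def test_afternoon_shading_sector_detected(self, clean_table, site):
        t = clean_table.copy()
        hour = t.start.hour.to_numpy()
        sw = t["SW_IN"].copy()
        sector = (hour >= 14) & (hour < 17)
        sw[sector] *= 0.25
        t["SW_IN"] = sw
        assert "SHADED" in codes(radiation_issue_check(t, site, QCConfig()))


class TestPhysicalRange:
    @pytest.fixture()
    def pot(self, clean_table, site):
        from fluxqaqc.solar import potential_radiation
        return potential_radiation(site, clean_table.start, 30)

    def test_rh_as_ratio_detected(self, clean_table):
        t = inject_fault(clean_table, FaultSpec("UNIT_RATIO", var="RH",
                                                magnitude=0.01))
        findings = physical_range_check(t)
        f = next(f for f in findings if f.code == "PERCENT_AS_RATIO")
        assert f.severity == Severity.ACTION_REQUIRED and f.variables == ("RH",)

    def test_hard_limit_violations_counted(self, clean_table):
        t = clean_table.copy()
        ta = t["TA"].copy()
        ta[:500] = 80.0  # impossible air temperature
        t["TA"] = ta
        f = next(f for f in physical_range_check(t) if f.code == "OUT_OF_RANGE")
        assert f.metrics["n_violations"] == 500
        assert f.severity == Severity.ACTION_REQUIRED

    def test_clean_silent(self, clean_table, pot):
        assert physical_range_check(clean_table, pot=pot) == []


class TestVariability:
    def test_constant_fill_span_recovered(self, clean_table):
        t = inject_fault(clean_table, FaultSpec(
            "CONSTANT_FILL", var="TA", magnitude=12.34,
            span=("202005100000", "202005130000")))
        f = next(f for f in variability_check(t) if f.code == "FILLED_CONSTANT")
        assert f.metrics["run_length"] == 3 * 48
        assert f.span_start == "202005100000" and f.span_end == "202005130000"
        assert f.metrics["value"] == 12.34

    def test_step_breakpoint_within_five_days(self, clean_table):
        from fluxqaqc.data_qaqc import mad
        delta = 3.0 * mad(clean_table["SWC_1_1_1"])
        t = inject_fault(clean_table, FaultSpec(
            "STEP_CHANGE", var="SWC_1_1_1", magnitude=delta,
            span=("202007010000", "202007010000")))
        f = next(f for f in variability_check(t) if f.code == "STEP_CHANGE")
        injected_day = (pd.Timestamp("2020-07-01") - pd.Timestamp("2020-01-01")).days
        assert abs(f.metrics["breakpoint_day"] - injected_day) <= 5

    def test_cutoff_plateau_detected(self, clean_table):
        bound = float(np.quantile(clean_table["WS"], 0.85))
        t = inject_fault(clean_table, FaultSpec("CUTOFF", var="WS", magnitude=bound))
        f = next(f for f in variability_check(t) if f.code == "CUTOFF")
        assert f.metrics["side"] == "max"
        assert f.metrics["fraction_at_extreme"] > 0.1

    def test_white_noise_type_one_error_rate(self):
        # a pure noise series should essentially never trigger the screens
        n_false = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            start, end = make_time_axis("2020-01-01", 48 * 200, 30)
            t = FPTable(start, end,
                        pd.DataFrame({"TA": rng.normal(10, 3, 48 * 200)}), 30)
            found = [f for f in variability_check(t)
                     if f.code in ("TREND", "STEP_CHANGE", "FILLED_CONSTANT",
                                   "CUTOFF")]
            n_false += bool(found)
        assert n_false / n_seeds < 0.05


class TestMultivariate:
    def test_derived_variable_perfect_fit(self, clean_table):
        t = clean_table.copy()
        t["PPFD_IN"] = 2.04 * t["SW_IN"]  # exactly derived, no noise
        findings = multivariate_check(t)
        f = next(f for f in findings if f.code == "PERFECT_FIT")
        assert f.metrics["r_squared"] > 0.9999

    def test_gain_drift_flags_slope_trend(self, clean_table):
        t = clean_table.copy()
        n = len(t)
        gain = np.linspace(2.04, 1.50, n)
        t["PPFD_IN"] = gain * t["SW_IN"] + (t["PPFD_IN"] - 2.04 * t["SW_IN"])
        assert "SLOPE_TREND" in codes(multivariate_check(t))

    def test_two_week_mismatch_window_found(self, clean_table):
        t = clean_table.copy()
        m = (t.start >= "2020-06-01") & (t.start < "2020-06-15")
        sw = t["SW_IN"].copy()
        sw[m] *= 0.5  # SW halves but PPFD does not
        t["SW_IN"] = sw
        findings = [f for f in multivariate_check(t, pairs=[("PPFD_IN", "SW_IN")])
                    if f.code == "SHORT_TERM_MISMATCH"]
        assert findings
        f = findings[0]
        assert "202006" in f.span_start

    def test_missing_pair_member_skipped(self, clean_table):
        t = clean_table.copy()
        t.data = t.data.drop(columns=["T_SONIC"])
        skipped_msgs = [f.message for f in multivariate_check(t)
                        if f.code == "SKIPPED"]
        assert any("T_SONIC" in m for m in skipped_msgs)

    def test_clean_silent(self, clean_table):
        real = [f for f in multivariate_check(clean_table) if f.code != "SKIPPED"]
        assert real == []


class TestDiurnalSeasonal:
    def test_clean_fc_no_sign_flip(self, clean_table, site):
        _, findings = diurnal_seasonal_check(clean_table, site)
        assert "SIGN_FLIP" not in codes(findings)

    def test_flipped_fc_detected(self, clean_table, site):
        t = inject_fault(clean_table, FaultSpec("SIGN_FLIP", var="FC"))
        _, findings = diurnal_seasonal_check(t, site)
        f = next(f for f in findings if f.code == "SIGN_FLIP")
        assert f.severity == Severity.ACTION_REQUIRED

    def test_composite_counts_conserve_nonmissing(self, clean_table):
        comp = diurnal_composite(clean_table, "FC")
        months = clean_table.start.strftime("%Y-%m")
        fc = clean_table["FC"]
        for i, m in enumerate(comp.months):
            assert comp.count[i].sum() == np.isfinite(fc[np.asarray(months == m)]).sum()

    def test_insufficient_months_skipped(self, site):
        t = generate_clean(SyntheticSiteConfig(seed=3, days=30))
        _, findings = diurnal_seasonal_check(t, site)
        assert "SKIPPED" in codes(findings)


class TestUstarFiltering:
    def test_clean_availability_flat_and_verdict_none(self, clean_table, site):
        result, findings = ustar_filtering_check(clean_table, site)
        assert result.verdicts == ()
        assert findings == []
        avail = result.availability[np.isfinite(result.availability)]
        assert avail.min() > 0.9  # no cliff anywhere

    @pytest.mark.parametrize("th", [0.1, 0.2, 0.3, 0.4])
    def test_threshold_recovered_within_one_bin(self, clean_table, site, th):
        t = inject_fault(clean_table, FaultSpec("USTAR_FILTER", magnitude=th))
        result, findings = ustar_filtering_check(t, site)
        assert "FC_FILTERED" in result.verdicts
        assert abs(result.threshold - th) <= 0.05
        assert result.threshold in result.bin_edges

    def test_truncated_ustar_distribution_detected(self, clean_table, site):
        t = clean_table.copy()
        us = t["USTAR"].copy()
        us[us < 0.15] = np.nan  # deleted rows below a floor
        t["USTAR"] = us
        result, findings = ustar_filtering_check(t, site)
        assert "USTAR_FILTERED" in result.verdicts

    def test_skipped_without_ustar(self, clean_table, site):
        t = clean_table.copy()
        t.data = t.data.drop(columns=["USTAR"])
        result, findings = ustar_filtering_check(t, site)
        assert result is None and codes(findings) == {"SKIPPED"}


class TestVariableCoverage:
    def test_all_empty_column(self, clean_table):
        t = clean_table.copy()
        t["SWC_1_1_1"] = np.full(len(t), np.nan)
        assert "EMPTY_COLUMN" in codes(variable_coverage_check(t))

    def test_interior_gap_beyond_tolerance(self, clean_table):
        t = inject_fault(clean_table, FaultSpec(
            "GAP", var="TS_1_1_1", span=("202006010000", "202008300000")))
        f = next(f for f in variable_coverage_check(t) if f.code == "LONG_GAP")
        assert f.variables == ("TS_1_1_1",)
        assert 89 <= f.metrics["gap_days"] <= 91

    def test_naming_mismatch_vs_prior(self, clean_table):
        findings = variable_coverage_check(
            clean_table, prior_labels=list(clean_table.columns[:-1]) + ["TA_1_1_1"])
        f = next(f for f in findings if f.code == "NAMING_MISMATCH")
        assert "TA_1_1_1" in f.metrics["missing_vs_prior"]

    def test_clean_without_prior_silent(self, clean_table):
        assert variable_coverage_check(clean_table) == []


class TestCombineWithPrior:
    def test_extension_concatenates(self):
        prior = generate_clean(SyntheticSiteConfig(seed=1, days=40))
        new = generate_clean(SyntheticSiteConfig(seed=1, days=20,
                                                 start="2020-02-10"))
        combined = combine_with_prior(new, prior)
        assert combined.start[0] == prior.start[0]
        assert combined.start[-1] == new.start[-1]
        assert combined.validate() == []

    def test_replacement_takes_new_values(self):
        prior = generate_clean(SyntheticSiteConfig(seed=1, days=40))
        new = generate_clean(SyntheticSiteConfig(seed=2, days=10,
                                                 start="2020-01-11"))
        combined = combine_with_prior(new, prior)
        sel = (combined.start >= new.start[0]) & (combined.start <= new.start[-1])
        np.testing.assert_array_equal(combined["TA"][sel], new["TA"])
        before = combined.start < new.start[0]
        np.testing.assert_array_equal(combined["TA"][before],
                                      prior["TA"][:before.sum()])

    def test_combine_with_nothing_is_identity(self, clean_table):
        assert combine_with_prior(clean_table, None).equals(clean_table)

    def test_resolution_mismatch_rejected(self):
        a = generate_clean(SyntheticSiteConfig(seed=1, days=5))
        b = generate_clean(SyntheticSiteConfig(seed=1, days=5,
                                               resolution_minutes=60))
        with pytest.raises(ValueError):
            combine_with_prior(a, b)


class TestRunDataQAQC:
    def test_multi_fault_record_yields_matching_findings(self, site):
        cfg = SyntheticSiteConfig(seed=11)
        t = generate_clean(cfg)
        from fluxqaqc.synthetic import inject_faults
        t = inject_faults(t, [
            FaultSpec("SIGN_FLIP", var="FC"),
            FaultSpec("UNIT_RATIO", var="RH", magnitude=0.01),
            FaultSpec("USTAR_FILTER", magnitude=0.3),
        ])
        rep = run_data_qaqc(t, site)
        got = {f.code for f in rep.findings}
        assert {"SIGN_FLIP", "PERCENT_AS_RATIO", "FC_FILTERED"} <= got
        assert rep.overall_status == Severity.ACTION_REQUIRED

    def test_padding_with_missing_rows_changes_no_verdict(self, site):
        cfg = SyntheticSiteConfig(seed=4, days=200)
        t = generate_clean(cfg)
        rep1 = run_data_qaqc(t, site)
        pad_n = 48 * 3
        start, end = make_time_axis(t.start[-1] + pd.Timedelta(minutes=30),
                                    pad_n, 30)
        pad = FPTable(start, end,
                      pd.DataFrame(np.nan, index=range(pad_n), columns=t.columns),
                      30, t.site_id)
        padded = FPTable(t.start.append(pad.start), t.end.append(pad.end),
                         pd.concat([t.data, pad.data], ignore_index=True),
                         30, t.site_id)
        rep2 = run_data_qaqc(padded, site)
        assert [(f.check, f.code) for f in rep1.findings] == \
            [(f.check, f.code) for f in rep2.findings]

    def test_deterministic_reports(self, site):
        cfg = SyntheticSiteConfig(seed=6, days=200)
        t = generate_clean(cfg)
        assert run_data_qaqc(t, site).to_json() == run_data_qaqc(t, site).to_json()
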