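"""The six data-quality checks for combined flux-met records.

Checks (pipeline order): timestamp alignment (including the radiation
issues that share its reference signal), physical range (including the
variability screens), multivariate comparison, diurnal-seasonal pattern,
USTAR filtering, and variable coverage.  Each check consumes an
:class:`~fluxqaqc.fp_format.FPTable` — the uploaded data combined with any
previously published record — and emits :class:`~fluxqaqc.reporting.Finding`
objects.  Checks only *detect*; correction is the site team's job.

Design conventions shared by the checks:

* nighttime is defined by computed potential radiation (``SW_IN_POT == 0``)
  so radiation-sensor faults cannot corrupt the day/night split;
* statistics are computed over non-missing values only, and long-gap
  screening looks at *interior* gaps, which together make every verdict
  invariant to padding the record with fully-missing rows;
* robust location/scale (median/MAD) everywhere a sensor fault could
  otherwise corrupt the reference statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import QCConfig
from .fp_format import FPTable, SiteMetadata, format_timestamp, parse_variable_name
from .registry import VariableRegistry
from .reporting import Finding, QAQCReport, Severity, assemble_report, skipped
from .solar import potential_radiation

DATA_CHECKS = [
    "timestamp_alignment", "physical_range", "multivariate",
    "diurnal_seasonal", "ustar_filtering", "variable_coverage",
]

DEFAULT_PAIRS = [("PPFD_IN", "SW_IN"), ("WS", "USTAR"),
                 ("T_SONIC", "TA"), ("NETRAD", "SW_IN")]

MINUTE_NS = 60 * 10**9
DAY_NS = 24 * 60 * MINUTE_NS


# ---------------------------------------------------------------------------
# small numeric helpers
# ---------------------------------------------------------------------------

def mad(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    if x.size == 0:
        return np.nan
    return float(np.median(np.abs(x - np.median(x))))


def robust_sigma(x: np.ndarray) -> float:
    return 1.4826 * mad(x)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 3:
        return np.nan
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _theil_sen(x: np.ndarray, y: np.ndarray, cap: int = 400) -> tuple[float, float]:
    """Theil-Sen slope on a deterministic subsample; intercept as the median
    of (y - slope*x) over *all* points, which stays unbiased when x is
    bimodal (e.g. a night cluster at zero radiation)."""
    n = x.size
    xs, ys = x, y
    if n > cap:
        sel = np.linspace(0, n - 1, cap).astype(int)
        xs, ys = x[sel], y[sel]
    if np.ptp(xs) == 0:
        return np.nan, np.nan
    slope = float(stats.theilslopes(ys, xs).slope)
    intercept = float(np.median(y - slope * x))
    return slope, intercept


def _base_of(label: str) -> str:
    try:
        return parse_variable_name(label).base.upper()
    except ValueError:
        return label.upper()


def _col_for_base(table: FPTable, base: str) -> Optional[str]:
    """First column whose base matches (prefers the unqualified label)."""
    matches = [c for c in table.columns if _base_of(c) == base]
    if not matches:
        return None
    matches.sort(key=lambda c: (len(c), c))
    return matches[0]


def _day_index(table: FPTable) -> np.ndarray:
    return ((table.start.asi8 - table.start.asi8[0]) // DAY_NS).astype(int)


def _span_finding_times(table: FPTable, i0: int, i1: int) -> tuple[str, str]:
    return format_timestamp(table.start[i0]), format_timestamp(table.end[i1])


def _longest_consecutive_run(values: np.ndarray) -> Optional[tuple[int, int]]:
    """(first, last) of the longest run of consecutive integers, or None."""
    if values.size == 0:
        return None
    values = np.sort(values)
    breaks = np.flatnonzero(np.diff(values) > 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [values.size - 1]))
    k = int(np.argmax(stops - starts))
    return int(values[starts[k]]), int(values[stops[k]])


def _interior_runs(missing: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of missing runs, excluding the record edges."""
    if missing.all() or not missing.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], missing.view(np.int8), [0]))))
    starts, stops = idx[0::2], idx[1::2]
    first_data = int(np.argmax(~missing))
    last_data = len(missing) - 1 - int(np.argmax(~missing[::-1]))
    return [(int(a), int(b)) for a, b in zip(starts, stops)
            if a > first_data and b - 1 < last_data]


# ---------------------------------------------------------------------------
# timestamp alignment
# ---------------------------------------------------------------------------

@dataclass
class LagProfile:
    """Per-window best lag (intervals) of measured radiation vs potential."""

    variable: str
    window_start_idx: np.ndarray
    lags: np.ndarray          # signed intervals; NaN-free only where valid
    peak_r: np.ndarray
    valid: np.ndarray         # window had enough coverage and correlation
    max_lag: int

    def modal_lag(self) -> Optional[int]:
        lags = self.lags[self.valid]
        if lags.size == 0:
            return None
        values, counts = np.unique(lags, return_counts=True)
        return int(values[np.argmax(counts)])


def _lag_profile(x: np.ndarray, pot: np.ndarray, table: FPTable, cfg: QCConfig
                 ) -> LagProfile:
    ipd = 24 * 60 // table.resolution_minutes
    wlen = cfg.window_days * ipd
    step = cfg.window_step_days * ipd
    n = len(x)
    starts = np.arange(0, max(n - wlen + 1, 1), step)
    lags = np.full(len(starts), 0, dtype=int)
    peak_r = np.full(len(starts), np.nan)
    valid = np.zeros(len(starts), dtype=bool)
    L_range = np.arange(-cfg.max_lag, cfg.max_lag + 1)

    for w, a in enumerate(starts):
        b = min(a + wlen, n)
        xs = x[a:b]
        day = pot[a:b] > 0
        usable = np.isfinite(xs) & day
        if day.sum() == 0 or usable.sum() / day.sum() < cfg.min_coverage:
            continue
        best_r, best_L = -np.inf, 0
        for L in L_range:
            lo, hi = a - L, b - L
            if lo < 0 or hi > n:
                off_lo = max(0, -lo)
                off_hi = min(0, n - hi) or None
                seg_x = xs[off_lo:off_hi]
                seg_p = pot[lo + off_lo: hi + (off_hi or 0)]
            else:
                seg_x, seg_p = xs, pot[lo:hi]
            m = np.isfinite(seg_x)
            r = _pearson(seg_x[m], seg_p[m])
            if np.isfinite(r) and r > best_r:
                best_r, best_L = r, int(L)
        if np.isfinite(best_r):
            lags[w], peak_r[w] = best_L, best_r
            valid[w] = best_r >= cfg.lag_r_min
    return LagProfile("", starts, lags, peak_r, valid, cfg.max_lag)


def _plateaus(values: np.ndarray) -> list[tuple[int, int]]:
    """(value, run length) for consecutive runs in a sequence."""
    out = []
    i = 0
    while i < len(values):
        j = i
        while j < len(values) and values[j] == values[i]:
            j += 1
        out.append((int(values[i]), j - i))
        i = j
    return out


def timestamp_alignment(table: FPTable, site: SiteMetadata, cfg: QCConfig,
                        pot: Optional[np.ndarray] = None
                        ) -> tuple[Optional[LagProfile], list[Finding]]:
    """Cross-correlate measured radiation against potential radiation over
    sliding windows and classify the lag pattern.

    Signatures: a constant nonzero lag of one interval is a beginning-vs-
    ending timestamp confusion (interval-midpoint evaluation makes that
    exact); a larger constant lag is a timestamp shift or time-zone
    mismatch; two season-long lag plateaus separated by one hour are
    daylight-saving time; radiation streams with different lags are not
    synchronized with each other.
    """
    check = "timestamp_alignment"
    if pot is None:
        pot = potential_radiation(site, table.start, table.resolution_minutes)
    ipd_hour = 60 // table.resolution_minutes

    profiles: dict[str, LagProfile] = {}
    for base in ("SW_IN", "PPFD_IN"):
        col = _col_for_base(table, base)
        if col is not None:
            prof = _lag_profile(table[col], pot, table, cfg)
            prof.variable = col
            profiles[base] = prof

    if not profiles or not any(p.valid.any() for p in profiles.values()):
        return None, [skipped(check, "no radiation variable with sufficient coverage")]

    primary_base = "SW_IN" if "SW_IN" in profiles and profiles["SW_IN"].valid.any() \
        else "PPFD_IN"
    prof = profiles[primary_base]
    findings: list[Finding] = []

    lags = prof.lags[prof.valid]
    values, counts = np.unique(lags, return_counts=True)
    modal = int(values[np.argmax(counts)])
    frac_modal = counts.max() / lags.size

    # DST signature: two plateaus separated by one hour of intervals
    dst = False
    if len(values) >= 2:
        top2 = values[np.argsort(counts)[-2:]]
        l1, l2 = sorted(int(v) for v in top2)
        runs = _plateaus(lags)
        run_len = {v: max((r for val, r in runs if val == v), default=0)
                   for v in (l1, l2)}
        cover = (counts[values == l1][0] + counts[values == l2][0]) / lags.size
        if (l2 - l1 == ipd_hour and cover >= 0.9
                and run_len[l1] >= cfg.dst_min_plateau
                and run_len[l2] >= cfg.dst_min_plateau):
            dst = True
            findings.append(Finding(
                check=check, code="DST", severity=Severity.ACTION_REQUIRED,
                variables=(prof.variable,),
                metrics={"plateau_lags": [l1, l2], "fraction": float(cover)},
                message="two season-long lag plateaus separated by one hour: "
                        "daylight-saving time appears to be encoded"))

    if not dst and modal != 0 and frac_modal >= cfg.lag_fraction:
        if abs(modal) == 1:
            findings.append(Finding(
                check=check, code="BEGIN_END_CONFUSION",
                severity=Severity.ACTION_REQUIRED, variables=(prof.variable,),
                metrics={"modal_lag": modal, "fraction": float(frac_modal)},
                message="persistent one-interval lag: beginning vs ending "
                        "timestamp convention appears swapped"))
        else:
            tz_note = (" (a whole number of hours: check the time-zone "
                       "specification)" if modal % ipd_hour == 0 else "")
            findings.append(Finding(
                check=check, code="TIMESTAMP_SHIFT",
                severity=Severity.ACTION_REQUIRED, variables=(prof.variable,),
                metrics={"modal_lag": modal, "fraction": float(frac_modal)},
                message=f"constant timestamp lag of {modal} interval(s) vs "
                        f"potential radiation{tz_note}"))

    if len(profiles) == 2:
        m_sw = profiles["SW_IN"].modal_lag()
        m_pp = profiles["PPFD_IN"].modal_lag()
        if m_sw is not None and m_pp is not None and m_sw != m_pp:
            findings.append(Finding(
                check=check, code="NOT_SYNCHRONIZED", severity=Severity.WARNING,
                variables=(profiles["SW_IN"].variable, profiles["PPFD_IN"].variable),
                metrics={"lag_sw_in": m_sw, "lag_ppfd_in": m_pp},
                message="SW_IN and PPFD_IN disagree on timestamp lag: "
                        "data streams not synchronized"))
    return prof, findings


# ---------------------------------------------------------------------------
# radiation issues (same module family as timestamp alignment)
# ---------------------------------------------------------------------------

def radiation_issue_check(table: FPTable, site: SiteMetadata, cfg: QCConfig,
                          pot: Optional[np.ndarray] = None) -> list[Finding]:
    """Ceiling, tilt, and shading screens on SW_IN against SW_IN_POT."""
    check = "timestamp_alignment"
    col = _col_for_base(table, "SW_IN")
    if col is None:
        return [skipped(check, "SW_IN not present: radiation issue check skipped")]
    if pot is None:
        pot = potential_radiation(site, table.start, table.resolution_minutes)
    x = table[col]
    findings: list[Finding] = []

    day = (pot > cfg.pot_floor) & np.isfinite(x)
    n_day = int(day.sum())
    if n_day < cfg.n_min:
        return [skipped(check, "too few daytime SW_IN values for radiation checks")]

    # (a) higher than expected readings
    over = day & (x > cfg.headroom * pot)
    frac_over = over.sum() / n_day
    if frac_over > cfg.excess_frac:
        findings.append(Finding(
            check=check, code="HIGH_RADIATION", severity=Severity.WARNING,
            variables=(col,),
            metrics={"fraction_above_ceiling": float(frac_over),
                     "headroom": cfg.headroom},
            message=f"{frac_over:.1%} of daytime SW_IN exceeds the potential-"
                    "radiation ceiling: check units, calibration or sensor"))

    ratio = np.where(day, x / np.where(pot > 0, pot, np.nan), np.nan)
    hour = table.start.hour.to_numpy() + table.start.minute.to_numpy() / 60.0
    month = table.start.month.to_numpy()

    # (b) tilt: persistent morning/afternoon clearness asymmetry
    diffs = []
    for m in range(1, 13):
        am = ratio[(month == m) & (hour < 12) & np.isfinite(ratio)]
        pm = ratio[(month == m) & (hour >= 12) & np.isfinite(ratio)]
        if am.size >= 30 and pm.size >= 30:
            diffs.append((m, float(np.median(am) - np.median(pm))))
    n_asym = sum(1 for _, d in diffs if abs(d) > cfg.asym_tol)
    if diffs and n_asym >= cfg.tilt_min_months:
        findings.append(Finding(
            check=check, code="TILTED", severity=Severity.WARNING, variables=(col,),
            metrics={"months_asymmetric": n_asym,
                     "max_abs_asymmetry": float(max(abs(d) for _, d in diffs))},
            message="persistent morning/afternoon clearness asymmetry: "
                    "radiation sensor may be tilted"))

    # (c) shading: a contiguous time-of-day sector depressed vs its month
    ipd_hour = 60 // table.resolution_minutes
    shade_months = 0
    shade_hours: tuple[float, float] | None = None
    for m in range(1, 13):
        sel = (month == m) & np.isfinite(ratio)
        if sel.sum() < 100:
            continue
        hb = np.floor(hour[sel]).astype(int)
        med_by_hour = {}
        for h in np.unique(hb):
            vals = ratio[sel][hb == h]
            if vals.size >= 5:
                med_by_hour[h] = np.median(vals)
        if len(med_by_hour) < 5:
            continue
        month_med = np.median(list(med_by_hour.values()))
        hours_sorted = sorted(med_by_hour)
        flags = [med_by_hour[h] < cfg.shade_tol * month_med for h in hours_sorted]
        # longest contiguous flagged run of hour bins
        best, cur, best_span = 0, 0, None
        start_h = None
        for h, f in zip(hours_sorted, flags):
            if f:
                cur += 1
                if start_h is None:
                    start_h = h
                if cur > best:
                    best, best_span = cur, (start_h, h)
            else:
                cur, start_h = 0, None
        if best * ipd_hour >= cfg.shade_min_bins:
            shade_months += 1
            shade_hours = best_span
    if shade_months >= cfg.shade_min_months:
        findings.append(Finding(
            check=check, code="SHADED", severity=Severity.WARNING, variables=(col,),
            metrics={"months_affected": shade_months,
                     "hour_sector": list(shade_hours) if shade_hours else []},
            message="a contiguous time-of-day sector shows depressed clearness: "
                    "possible shading of the radiation sensor"))
    return findings


# ---------------------------------------------------------------------------
# physical range
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlausibleRange:
    """Site-specific plausible bounds for one variable in one season and
    day/night class.  The spread is asymmetric (separate MAD of the
    deviations above and below the median) so skewed distributions such as
    friction velocity or daytime radiation get one-sided headroom instead
    of spurious outliers."""

    variable: str
    season: str
    daytime: bool
    center: float
    spread: float         # overall MAD (reported)
    lower: float
    upper: float


_SEASON_OF_MONTH = {12: "DJF", 1: "DJF", 2: "DJF", 3: "MAM", 4: "MAM", 5: "MAM",
                    6: "JJA", 7: "JJA", 8: "JJA", 9: "SON", 10: "SON", 11: "SON"}


def _day_mask(table: FPTable, pot: Optional[np.ndarray]) -> np.ndarray:
    if pot is not None:
        return pot > 0
    hour = table.start.hour.to_numpy()
    return (hour >= 6) & (hour < 18)


def compute_plausible_ranges(table: FPTable, registry: VariableRegistry,
                             cfg: QCConfig,
                             pot: Optional[np.ndarray] = None
                             ) -> list[PlausibleRange]:
    """Median +/- k*MAD bounds per variable, meteorological season and
    day/night class, clipped to the registry hard limits."""
    months = table.start.month.to_numpy()
    seasons = np.array([_SEASON_OF_MONTH[m] for m in months])
    day = _day_mask(table, pot)
    out: list[PlausibleRange] = []
    for col in table.columns:
        entry = registry.lookup(_base_of(col))
        if entry is None:
            continue
        x = table[col]
        for season in ("DJF", "MAM", "JJA", "SON"):
            for is_day in (True, False):
                sel = (seasons == season) & (day == is_day) & np.isfinite(x)
                vals = x[sel]
                if vals.size < 30:
                    continue
                center = float(np.median(vals))
                dev = vals - center
                spread = float(np.median(np.abs(dev)))
                up = dev[dev > 0]
                down = -dev[dev < 0]
                mad_up = float(np.median(up)) if up.size >= 10 else spread
                mad_down = float(np.median(down)) if down.size >= 10 else spread
                if not np.isfinite(spread) or spread == 0:
                    continue
                lower = max(center - cfg.outlier_k * mad_down, entry.hard_min)
                upper = min(center + cfg.outlier_k * mad_up, entry.hard_max)
                if lower >= upper:
                    continue
                out.append(PlausibleRange(col, season, is_day, center, spread,
                                          lower, upper))
    return out


def physical_range_check(table: FPTable, registry: Optional[VariableRegistry] = None,
                         ranges: Optional[list[PlausibleRange]] = None,
                         cfg: Optional[QCConfig] = None,
                         pot: Optional[np.ndarray] = None) -> list[Finding]:
    """Hard-limit violations, plausible-range outliers, and the
    percent-vs-ratio units screen."""
    check = "physical_range"
    registry = registry or VariableRegistry.default()
    cfg = cfg or QCConfig()
    if ranges is None:
        ranges = compute_plausible_ranges(table, registry, cfg, pot=pot)
    months = table.start.month.to_numpy()
    seasons = np.array([_SEASON_OF_MONTH[m] for m in months])
    day = _day_mask(table, pot)
    by_var: dict[str, list[PlausibleRange]] = {}
    for r in ranges:
        by_var.setdefault(r.variable, []).append(r)

    findings: list[Finding] = []
    for col in table.columns:
        entry = registry.lookup(_base_of(col))
        if entry is None:
            continue
        x = table[col]
        finite = np.isfinite(x)
        n = int(finite.sum())
        if n == 0:
            continue

        hard_bad = finite & ((x < entry.hard_min) | (x > entry.hard_max))
        if hard_bad.any():
            findings.append(Finding(
                check=check, code="OUT_OF_RANGE", severity=Severity.ACTION_REQUIRED,
                variables=(col,),
                metrics={"n_violations": int(hard_bad.sum()),
                         "hard_min": entry.hard_min, "hard_max": entry.hard_max},
                message=f"{int(hard_bad.sum())} values outside the physical limits "
                        f"[{entry.hard_min}, {entry.hard_max}] {entry.units}"))

        if n >= cfg.n_min and col in by_var:
            out_mask = np.zeros(len(x), dtype=bool)
            for r in by_var[col]:
                sel = (seasons == r.season) & (day == r.daytime) & finite
                out_mask |= sel & ((x < r.lower) | (x > r.upper))
            frac = out_mask.sum() / n
            if frac > cfg.outlier_frac:
                findings.append(Finding(
                    check=check, code="EXCESSIVE_OUTLIERS", severity=Severity.WARNING,
                    variables=(col,),
                    metrics={"outlier_fraction": float(frac), "k_mad": cfg.outlier_k},
                    message=f"{frac:.2%} of values fall outside the site-specific "
                            "plausible range"))

        if entry.is_percent and n >= cfg.n_min:
            vmax = float(np.nanmax(x))
            if vmax <= cfg.percent_max:
                findings.append(Finding(
                    check=check, code="PERCENT_AS_RATIO",
                    severity=Severity.ACTION_REQUIRED, variables=(col,),
                    metrics={"max_value": vmax},
                    message=f"maximum {vmax:.3g} for a percent variable: values "
                            "appear to be ratios (0-1) instead of percent (0-100)"))
    return findings


# ---------------------------------------------------------------------------
# variability (trend / step / constants / cut-off)
# ---------------------------------------------------------------------------

def _daily_medians(table: FPTable, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    days = _day_index(table)
    frame = pd.DataFrame({"d": days, "x": x})
    grouped = frame.dropna().groupby("d")["x"].median()
    return grouped.index.to_numpy(), grouped.to_numpy()


def _harmonic_design(t_years: np.ndarray) -> np.ndarray:
    w = 2 * np.pi * t_years
    return np.column_stack([np.ones_like(t_years), t_years,
                            np.sin(w), np.cos(w), np.sin(2 * w), np.cos(2 * w)])


def variability_check(table: FPTable, cfg: Optional[QCConfig] = None,
                      registry: Optional[VariableRegistry] = None) -> list[Finding]:
    """Trend, step change, filled constants and cut-off plateaus.

    Trend and step operate on daily medians after removing a linear +
    annual/semiannual harmonic background, so seasonal cycles in a full-year
    record do not masquerade as drift or steps.
    """
    check = "physical_range"
    cfg = cfg or QCConfig()
    registry = registry or VariableRegistry.default()
    findings: list[Finding] = []

    for col in table.columns:
        entry = registry.lookup(_base_of(col))
        if entry is not None and entry.kind == "quality_flag":
            continue
        x = table[col]
        finite = np.isfinite(x)
        if finite.sum() < cfg.n_min:
            continue

        # -- filled constants (half-hourly runs of identical values)
        same = np.concatenate(([False], (x[1:] == x[:-1]) & finite[1:] & finite[:-1]))
        run_len, run_start, best_len, best_start = 0, 0, 0, 0
        for i, s in enumerate(same):
            if s:
                if run_len == 0:
                    run_start = i - 1
                    run_len = 1
                run_len += 1
                if run_len > best_len:
                    best_len, best_start = run_len, run_start
            else:
                run_len = 0
        if best_len >= cfg.run_min:
            s0, s1 = best_start, best_start + best_len - 1
            span = _span_finding_times(table, s0, s1)
            findings.append(Finding(
                check=check, code="FILLED_CONSTANT", severity=Severity.WARNING,
                variables=(col,), span_start=span[0], span_end=span[1],
                metrics={"run_length": int(best_len), "value": float(x[s0])},
                message=f"run of {best_len} identical values "
                        f"({float(x[s0]):.6g}): repeated pattern or filled constant"))

        # -- cut-off: probability mass piled at an interior extreme
        vals = x[finite]
        if vals.size >= cfg.n_min and not (entry is not None and entry.kind == "radiation"):
            for side, extreme, hard in (
                    ("min", float(vals.min()), entry.hard_min if entry else -np.inf),
                    ("max", float(vals.max()), entry.hard_max if entry else np.inf)):
                if entry is not None and np.isclose(extreme, hard):
                    continue  # physical saturation at a hard limit, not a cut-off
                n_at = int(np.isclose(vals, extreme).sum())
                frac = n_at / vals.size
                if frac > cfg.cutoff_frac and n_at >= 20:
                    findings.append(Finding(
                        check=check, code="CUTOFF", severity=Severity.WARNING,
                        variables=(col,),
                        metrics={"side": side, "value": extreme,
                                 "fraction_at_extreme": float(frac)},
                        message=f"{frac:.2%} of values sit exactly at the series "
                                f"{side} ({extreme:.6g}): measurement or "
                                "processing cut-off"))
                    break

        # -- trend and step change on seasonally adjusted daily medians.
        # Only slowly varying state variables: radiation and flux drift is
        # screened against reference signals (potential radiation, paired
        # variables) where a harmonic background would be misspecified.
        if entry is None or entry.kind not in ("meteorology", "soil", "concentration"):
            continue
        days, daily = _daily_medians(table, x)
        if days.size < 120:
            continue
        t_years = days / 365.25
        X = _harmonic_design(t_years)
        beta, *_ = np.linalg.lstsq(X, daily, rcond=None)
        resid = daily - X @ beta
        sigma = robust_sigma(resid)
        if not np.isfinite(sigma) or sigma == 0:
            continue
        span_years = float(t_years[-1] - t_years[0])

        # trend: the linear coefficient of the joint fit, gated on both its
        # t-statistic and a material magnitude.  (On partial-year records
        # the harmonics are collinear with the linear term; the t-statistic
        # absorbs that through its inflated standard error.)
        xtx_inv = np.linalg.pinv(X.T @ X)
        slope = float(beta[1])
        se_slope = sigma * float(np.sqrt(max(xtx_inv[1, 1], 1e-30)))
        t_trend = abs(slope) / se_slope if se_slope > 0 else 0.0
        if t_trend > cfg.trend_t_tol and abs(slope) * span_years > cfg.trend_tol * sigma:
            findings.append(Finding(
                check=check, code="TREND", severity=Severity.WARNING,
                variables=(col,),
                metrics={"slope_per_year": float(slope),
                         "total_change": float(slope * span_years),
                         "t_statistic": float(t_trend),
                         "robust_sigma": sigma},
                message=f"systematic drift of {slope * span_years:.3g} "
                        f"{entry.units if entry else ''} over the record"))

        # sup-t scan: a step term fitted jointly with the harmonic
        # background at every candidate breakpoint, so seasonality neither
        # masks nor mimics a step
        m = cfg.step_min_seg_days
        nr = daily.size
        if nr >= 2 * m:
            H = X @ np.linalg.pinv(X.T @ X) @ X.T
            yperp = daily - H @ daily
            best_t, best_b = 0.0, None
            for b in range(m, nr - m):
                s = np.zeros(nr)
                s[b:] = 1.0
                u = s - H @ s
                uu = float(u @ u)
                if uu < 1e-9:
                    continue
                d = float(u @ yperp) / uu
                sig_b = robust_sigma(yperp - d * u)
                if sig_b <= 0:
                    continue
                t_b = abs(d) * np.sqrt(uu) / sig_b
                if t_b > best_t:
                    best_t, best_b = t_b, b
            if best_b is not None and best_t > cfg.step_tol:
                day_at = int(days[best_b])
                idx = int(np.searchsorted(_day_index(table), day_at))
                findings.append(Finding(
                    check=check, code="STEP_CHANGE", severity=Severity.WARNING,
                    variables=(col,),
                    span_start=format_timestamp(table.start[min(idx, len(table) - 1)]),
                    span_end=format_timestamp(table.end[-1]),
                    metrics={"step_t_statistic": float(best_t),
                             "breakpoint_day": day_at},
                    message=f"mean shift (t = {best_t:.1f}) at day {day_at} "
                            "of the record"))
    return findings


# ---------------------------------------------------------------------------
# multivariate comparison
# ---------------------------------------------------------------------------

def multivariate_check(table: FPTable, cfg: Optional[QCConfig] = None,
                       pairs: Optional[Sequence[tuple[str, str]]] = None
                       ) -> list[Finding]:
    """Regression screens between physically coupled variable pairs."""
    check = "multivariate"
    cfg = cfg or QCConfig()
    pairs = pairs if pairs is not None else DEFAULT_PAIRS
    findings: list[Finding] = []
    days = _day_index(table)

    for ybase, xbase in pairs:
        ycol, xcol = _col_for_base(table, ybase), _col_for_base(table, xbase)
        pair_name = f"{ybase}~{xbase}"
        if ycol is None or xcol is None:
            findings.append(skipped(check, f"pair {pair_name}: variable not present"))
            continue
        y, x = table[ycol], table[xcol]
        joint = np.isfinite(y) & np.isfinite(x)
        n = int(joint.sum())
        if n < cfg.mv_min_pts:
            findings.append(skipped(check, f"pair {pair_name}: insufficient joint coverage"))
            continue

        slope, intercept = _theil_sen(x[joint], y[joint], cap=cfg.mv_subsample)
        if not np.isfinite(slope):
            findings.append(skipped(check, f"pair {pair_name}: no spread in {xbase}"))
            continue
        res = np.where(joint, y - (intercept + slope * x), np.nan)
        gmad = mad(res)
        gsigma = 1.4826 * gmad if gmad > 0 else np.nan

        r = _pearson(x[joint], y[joint])
        if np.isfinite(r) and r * r > cfg.r2_perfect:
            findings.append(Finding(
                check=check, code="PERFECT_FIT", severity=Severity.WARNING,
                variables=(ycol, xcol), metrics={"r_squared": float(r * r)},
                message=f"{pair_name}: R^2 = {r * r:.6f}; one variable appears "
                        "derived from the other"))

        if np.isfinite(gsigma):
            # residual scale conditional on x so multiplicative noise does
            # not masquerade as outliers
            xj, rj = x[joint], res[joint]
            qs = np.nanquantile(xj, np.linspace(0, 1, 11))
            edges = np.unique(qs)
            which = np.clip(np.searchsorted(edges, xj, side="right") - 1,
                            0, max(len(edges) - 2, 0))
            local_mad = np.full(len(edges) - 1 if len(edges) > 1 else 1, gmad)
            for bidx in range(local_mad.size):
                seg = rj[which == bidx]
                if seg.size >= 50:
                    local_mad[bidx] = max(mad(seg), 1e-12)
            n_out = int((np.abs(rj) > cfg.mv_outlier_k * local_mad[which]).sum())
            frac = n_out / n
            if frac > cfg.mv_outlier_frac:
                findings.append(Finding(
                    check=check, code="OUTLIER", severity=Severity.WARNING,
                    variables=(ycol, xcol),
                    metrics={"outlier_fraction": float(frac), "k_mad": cfg.mv_outlier_k},
                    message=f"{pair_name}: {frac:.2%} of residuals beyond "
                            f"{cfg.mv_outlier_k} MAD"))

        # short-term mismatch: a run of days whose median residual (over the
        # informative upper half of the x range) departs from the fit
        if np.isfinite(gsigma):
            active = joint & (x > float(np.median(x[joint])))
            frame = pd.DataFrame({"d": days[active], "r": res[active]})
            g = frame.groupby("d")["r"].agg(["median", "count"])
            g = g[g["count"] >= 10]
            flagged = g.index.to_numpy()[
                np.abs(g["median"].to_numpy()) > cfg.mv_bias_tol * gsigma]
            run = _longest_consecutive_run(flagged)
            if run is not None and run[1] - run[0] + 1 >= cfg.mismatch_min_days:
                didx = _day_index(table)
                i0 = int(np.searchsorted(didx, run[0]))
                i1 = int(np.searchsorted(didx, run[1] + 1)) - 1
                span = _span_finding_times(table, i0, i1)
                findings.append(Finding(
                    check=check, code="SHORT_TERM_MISMATCH", severity=Severity.WARNING,
                    variables=(ycol, xcol),
                    span_start=span[0], span_end=span[1],
                    metrics={"n_days": int(run[1] - run[0] + 1),
                             "global_sigma": float(gsigma)},
                    message=f"{pair_name}: residuals depart from the overall "
                            "relationship for a sustained period"))

        # windowed slope for trend / step screens
        wdays = cfg.mv_window_days
        w_idx = days // wdays
        slopes = []
        for w in np.unique(w_idx):
            sel = joint & (w_idx == w)
            if sel.sum() < cfg.mv_min_pts:
                continue
            s_w, _ = _theil_sen(x[sel], y[sel], cap=cfg.mv_subsample)
            if np.isfinite(s_w):
                slopes.append(s_w)
        slopes_arr = np.asarray(slopes)

        if slopes_arr.size >= 6:
            ref = float(np.median(slopes_arr))
            if ref != 0:
                widx = np.arange(slopes_arr.size, dtype=float)
                drift_slope, _ = _theil_sen(widx, slopes_arr)
                rel_drift = abs(drift_slope) * (slopes_arr.size - 1) / abs(ref)
                if rel_drift > cfg.mv_drift_tol:
                    findings.append(Finding(
                        check=check, code="SLOPE_TREND", severity=Severity.WARNING,
                        variables=(ycol, xcol),
                        metrics={"relative_slope_drift": float(rel_drift),
                                 "median_slope": ref},
                        message=f"{pair_name}: regression slope drifts "
                                f"{rel_drift:.1%} across the record"))
                # two-segment step in the windowed slope
                best_step = 0.0
                for bpt in range(2, slopes_arr.size - 1):
                    d = abs(slopes_arr[:bpt].mean() - slopes_arr[bpt:].mean())
                    best_step = max(best_step, d)
                if best_step / abs(ref) > cfg.mv_step_tol and rel_drift <= cfg.mv_drift_tol:
                    findings.append(Finding(
                        check=check, code="SLOPE_STEP", severity=Severity.WARNING,
                        variables=(ycol, xcol),
                        metrics={"relative_slope_step": float(best_step / abs(ref))},
                        message=f"{pair_name}: step change in the regression slope"))
    return findings


# ---------------------------------------------------------------------------
# diurnal-seasonal pattern
# ---------------------------------------------------------------------------

@dataclass
class DiurnalComposite:
    """Median diurnal cycle by month with interquartile band and counts."""

    variable: str
    months: list[str]               # "YYYY-MM"
    median: np.ndarray              # (n_months, bins)
    q25: np.ndarray
    q75: np.ndarray
    count: np.ndarray
    bins: int


def diurnal_composite(table: FPTable, col: str,
                      values: Optional[np.ndarray] = None) -> DiurnalComposite:
    bins = 24 * 60 // table.resolution_minutes
    x = values if values is not None else table[col]
    tod = (table.start.hour.to_numpy() * 60 + table.start.minute.to_numpy()) \
        // table.resolution_minutes
    ym = table.start.strftime("%Y-%m")
    frame = pd.DataFrame({"ym": ym, "tod": tod, "x": x})
    months = sorted(frame.loc[np.isfinite(x), "ym"].unique())
    med = np.full((len(months), bins), np.nan)
    q25 = np.full_like(med, np.nan)
    q75 = np.full_like(med, np.nan)
    cnt = np.zeros((len(months), bins), dtype=int)
    g = frame.dropna().groupby(["ym", "tod"])["x"]
    stats_df = g.agg(median="median",
                     q25=lambda s: s.quantile(0.25),
                     q75=lambda s: s.quantile(0.75), count="count")
    m_index = {m: i for i, m in enumerate(months)}
    for (m, t), row in stats_df.iterrows():
        i, j = m_index[m], int(t)
        med[i, j], q25[i, j], q75[i, j] = row["median"], row["q25"], row["q75"]
        cnt[i, j] = int(row["count"])
    return DiurnalComposite(col, months, med, q25, q75, cnt, bins)


def _composite_lag(a: np.ndarray, b: np.ndarray, max_lag: int) -> Optional[int]:
    """Best lag (bins) aligning composite a to composite b."""
    best_r, best_L = -np.inf, None
    n = len(a)
    for L in range(-max_lag, max_lag + 1):
        if L >= 0:
            seg_a, seg_b = a[L:], b[:n - L]
        else:
            seg_a, seg_b = a[:n + L], b[-L:]
        m = np.isfinite(seg_a) & np.isfinite(seg_b)
        r = _pearson(seg_a[m], seg_b[m])
        if np.isfinite(r) and r > best_r:
            best_r, best_L = r, L
    return best_L


def diurnal_seasonal_check(table: FPTable, site: SiteMetadata,
                           cfg: Optional[QCConfig] = None,
                           pot: Optional[np.ndarray] = None,
                           registry: Optional[VariableRegistry] = None
                           ) -> tuple[dict[str, DiurnalComposite], list[Finding]]:
    """Sign-convention, timing and range screens on median diurnal composites."""
    check = "diurnal_seasonal"
    cfg = cfg or QCConfig()
    registry = registry or VariableRegistry.default()
    if pot is None:
        pot = potential_radiation(site, table.start, table.resolution_minutes)
    findings: list[Finding] = []
    composites: dict[str, DiurnalComposite] = {}

    pot_comp = diurnal_composite(table, "SW_IN_POT", values=pot)
    composites["SW_IN_POT"] = pot_comp
    pot_by_month = {m: pot_comp.median[i] for i, m in enumerate(pot_comp.months)}

    fc_col = _col_for_base(table, "FC") or _col_for_base(table, "FCH4")
    sw_col = _col_for_base(table, "SW_IN")

    if fc_col is None and sw_col is None:
        return composites, [skipped(check, "no flux or radiation variable present")]

    # -- sign convention (carbon flux)
    if fc_col is not None:
        comp = diurnal_composite(table, fc_col)
        composites[fc_col] = comp
        if len(comp.months) < cfg.min_months:
            findings.append(skipped(check, "fewer than "
                                    f"{cfg.min_months} months of {fc_col}"))
        else:
            amps, flips = [], []
            for i, m in enumerate(comp.months):
                pc = pot_by_month.get(m)
                if pc is None:
                    continue
                day_bins = pc > 50.0
                c = comp.median[i]
                day_med = np.nanmedian(c[day_bins]) if day_bins.any() else np.nan
                night_med = np.nanmedian(c[~day_bins]) if (~day_bins).any() else np.nan
                if not (np.isfinite(day_med) and np.isfinite(night_med)):
                    continue
                amp = abs(day_med - night_med)
                mfin = np.isfinite(c) & np.isfinite(pc)
                corr = _pearson(c[mfin], pc[mfin])
                amps.append((m, amp, day_med, night_med, corr))
            if amps:
                max_amp = max(a for _, a, *_ in amps)
                growing = [t for t in amps if t[1] >= cfg.growing_amp_frac * max_amp]
                flips = [t for t in growing
                         if t[2] > t[3] + cfg.sign_margin and (t[4] or 0) > 0.5]
                if growing and len(flips) >= cfg.sign_min_frac * len(growing):
                    findings.append(Finding(
                        check=check, code="SIGN_FLIP",
                        severity=Severity.ACTION_REQUIRED, variables=(fc_col,),
                        metrics={"months_flagged": len(flips),
                                 "growing_months": len(growing)},
                        message=f"daytime {fc_col} composite exceeds nighttime and "
                                "tracks radiation positively in the growing season: "
                                "sign convention appears flipped (uptake should be "
                                "negative)"))

    # -- timing: monthly composite lag vs potential radiation
    if sw_col is not None:
        comp = diurnal_composite(table, sw_col)
        composites[sw_col] = comp
        lags = []
        for i, m in enumerate(comp.months):
            pc = pot_by_month.get(m)
            if pc is None:
                continue
            L = _composite_lag(comp.median[i], pc, cfg.composite_lag_bins)
            if L is not None:
                lags.append(L)
        if lags:
            values, counts = np.unique(lags, return_counts=True)
            modal = int(values[np.argmax(counts)])
            if modal != 0 and counts.max() / len(lags) >= cfg.composite_lag_frac:
                findings.append(Finding(
                    check=check, code="DIURNAL_SHIFT", severity=Severity.WARNING,
                    variables=(sw_col,),
                    metrics={"modal_lag_bins": modal},
                    message="monthly diurnal composites are displaced from "
                            "potential radiation: corroborates a timestamp shift"))

    # -- physically unlikely composite values
    for col, comp in list(composites.items()):
        if col == "SW_IN_POT":
            continue
        entry = registry.lookup(_base_of(col))
        if entry is None:
            continue
        bad = np.isfinite(comp.median) & ((comp.median < entry.hard_min)
                                          | (comp.median > entry.hard_max))
        if bad.any():
            findings.append(Finding(
                check=check, code="UNLIKELY_VALUES", severity=Severity.WARNING,
                variables=(col,), metrics={"n_bins": int(bad.sum())},
                message=f"{col}: composite medians fall outside physical limits"))

    # -- year-over-year displacement of same-calendar-month composites
    for col, comp in list(composites.items()):
        if col == "SW_IN_POT" or len(comp.months) < 13:
            continue
        by_cal: dict[str, list[int]] = {}
        for i, m in enumerate(comp.months):
            by_cal.setdefault(m[5:], []).append(i)
        disps = []
        scale = robust_sigma(comp.median[np.isfinite(comp.median)])
        for cal, idxs in by_cal.items():
            if len(idxs) < 2 or not np.isfinite(scale) or scale == 0:
                continue
            a, b = comp.median[idxs[0]], comp.median[idxs[-1]]
            m2 = np.isfinite(a) & np.isfinite(b)
            if m2.sum() >= 10:
                disps.append(abs(float(np.median(b[m2] - a[m2]))) / scale)
        if disps and np.median(disps) > cfg.yoy_step_tol:
            findings.append(Finding(
                check=check, code="FULL_RANGE_STEP", severity=Severity.WARNING,
                variables=(col,),
                metrics={"median_displacement_sigma": float(np.median(disps))},
                message=f"{col}: year-over-year displacement of the diurnal "
                        "composite suggests a step in the full range"))
    return composites, findings


# ---------------------------------------------------------------------------
# USTAR filtering
# ---------------------------------------------------------------------------

@dataclass
class UstarFinding:
    """Nighttime FC availability by USTAR bin and the detected threshold."""

    bin_edges: np.ndarray
    availability: np.ndarray     # NaN for bins with too few samples
    counts: np.ndarray
    threshold: Optional[float]   # detected u* threshold (a bin edge) or None
    verdicts: tuple[str, ...]    # subset of {"FC_FILTERED", "USTAR_FILTERED"}


def ustar_filtering_check(table: FPTable, site: SiteMetadata,
                          cfg: Optional[QCConfig] = None,
                          pot: Optional[np.ndarray] = None
                          ) -> tuple[Optional[UstarFinding], list[Finding]]:
    """Detect pre-filtered nighttime carbon flux or truncated USTAR.

    Nighttime USTAR is binned (0.05 m s-1 wide); a cliff in FC availability
    below some bin edge while availability is healthy above it indicates the
    site team already applied a u* filter; a nighttime USTAR distribution
    whose 1st percentile sits above a floor indicates USTAR itself was
    filtered.
    """
    check = "ustar_filtering"
    cfg = cfg or QCConfig()
    fc_col = _col_for_base(table, "FC")
    us_col = _col_for_base(table, "USTAR")
    if fc_col is None or us_col is None:
        return None, [skipped(check, "FC and USTAR are both required")]
    if pot is None:
        pot = potential_radiation(site, table.start, table.resolution_minutes)

    night = pot == 0.0
    us = table[us_col]
    fc = table[fc_col]
    sel = night & np.isfinite(us)
    if sel.sum() < cfg.n_night:
        return None, [skipped(check, "too few nighttime USTAR observations")]

    edges = np.arange(0.0, cfg.ustar_max + cfg.ustar_bin_width / 2, cfg.ustar_bin_width)
    nbins = len(edges) - 1
    which = np.clip(np.digitize(us[sel], edges) - 1, 0, nbins - 1)
    fc_ok = np.isfinite(fc[sel])
    counts = np.bincount(which, minlength=nbins)
    ok_counts = np.bincount(which, weights=fc_ok.astype(float), minlength=nbins)
    avail = np.full(nbins, np.nan)
    considered = counts >= cfg.ustar_bin_min_count
    avail[considered] = ok_counts[considered] / counts[considered]

    threshold = None
    verdicts: list[str] = []
    findings: list[Finding] = []
    for j in range(1, nbins):
        below = avail[:j][considered[:j]]
        above_n = counts[j:][considered[j:]].sum()
        above_ok = ok_counts[j:][considered[j:]].sum()
        if below.size == 0 or above_n == 0:
            continue
        if (below < cfg.low_avail).all() and above_ok / above_n >= cfg.high_avail:
            threshold = float(edges[j])
    if threshold is not None:
        verdicts.append("FC_FILTERED")
        findings.append(Finding(
            check=check, code="FC_FILTERED", severity=Severity.WARNING,
            variables=(fc_col, us_col),
            metrics={"ustar_threshold": threshold},
            message=f"nighttime {fc_col} availability collapses below "
                    f"USTAR = {threshold:.2f} m s-1: data appear u*-filtered "
                    "before upload (unfiltered fluxes are preferred)"))

    p1 = float(np.percentile(us[sel], 1))
    if p1 > cfg.ustar_floor:
        verdicts.append("USTAR_FILTERED")
        findings.append(Finding(
            check=check, code="USTAR_FILTERED", severity=Severity.WARNING,
            variables=(us_col,),
            metrics={"night_p01": p1, "floor": cfg.ustar_floor},
            message=f"nighttime USTAR 1st percentile ({p1:.3f} m s-1) sits above "
                    f"{cfg.ustar_floor} m s-1: the distribution looks truncated"))

    result = UstarFinding(edges, avail, counts, threshold, tuple(verdicts))
    return result, findings


# ---------------------------------------------------------------------------
# variable coverage
# ---------------------------------------------------------------------------

def variable_coverage_check(table: FPTable,
                            prior_labels: Optional[Sequence[str]] = None,
                            cfg: Optional[QCConfig] = None) -> list[Finding]:
    """Long interior gaps, empty columns, mandatory variables, and label
    consistency against the previously published record."""
    check = "variable_coverage"
    cfg = cfg or QCConfig()
    findings: list[Finding] = []
    ipd = 24 * 60 // table.resolution_minutes

    bases = []
    for col in table.columns:
        x = table[col]
        finite = np.isfinite(x)
        if finite.any():
            bases.append(_base_of(col))
        if not finite.any():
            findings.append(Finding(
                check=check, code="EMPTY_COLUMN", severity=Severity.WARNING,
                variables=(col,), message=f"{col} contains no data at all"))
            continue
        runs = _interior_runs(~finite)
        if runs:
            a, b = max(runs, key=lambda r: r[1] - r[0])
            days = (b - a) / ipd
            if days > cfg.gap_tol_days:
                span = _span_finding_times(table, a, b - 1)
                findings.append(Finding(
                    check=check, code="LONG_GAP", severity=Severity.WARNING,
                    variables=(col,), span_start=span[0], span_end=span[1],
                    metrics={"gap_days": float(days)},
                    message=f"{col}: longest gap spans {days:.0f} days"))

    if not any(b in ("FC", "FCH4") for b in bases):
        findings.append(Finding(
            check=check, code="MISSING_MANDATORY", severity=Severity.WARNING,
            message="no carbon flux variable (FC or FCH4) with data in the "
                    "combined record"))

    if prior_labels is not None:
        cur = set(table.columns)
        prior = set(prior_labels)
        only_prior = sorted(prior - cur)
        only_new = sorted(cur - prior)
        if only_prior or only_new:
            findings.append(Finding(
                check=check, code="NAMING_MISMATCH", severity=Severity.WARNING,
                metrics={"missing_vs_prior": only_prior, "new_vs_prior": only_new},
                message="uploaded variable labels disagree with the previously "
                        f"published record (missing: {only_prior}, new: {only_new})"))
    return findings


# ---------------------------------------------------------------------------
# combining uploads with the published record
# ---------------------------------------------------------------------------

def combine_with_prior(new: FPTable, prior: Optional[FPTable]) -> FPTable:
    """Union of the new upload with the previously published record.

    Rows whose start timestamp falls inside the new table's axis come
    entirely from the new upload (replacement semantics); the label set is
    the union, with absent cells missing.
    """
    if prior is None or len(prior) == 0:
        return new.copy()
    if new.resolution_minutes != prior.resolution_minutes:
        raise ValueError("resolution mismatch between upload and prior record")
    if new.site_id and prior.site_id and new.site_id != prior.site_id:
        raise ValueError("site mismatch between upload and prior record")
    step = pd.Timedelta(minutes=new.resolution_minutes)
    t0 = min(new.start[0], prior.start[0])
    t1 = max(new.start[-1], prior.start[-1])
    full = pd.date_range(t0, t1, freq=step)
    cols = list(dict.fromkeys(prior.columns + new.columns))

    prior_df = prior.data.set_index(prior.start).reindex(full)
    new_df = new.data.set_index(new.start).reindex(full)
    in_new = full.isin(new.start)
    out = pd.DataFrame(index=full)
    for c in cols:
        p = prior_df[c] if c in prior_df else pd.Series(np.nan, index=full)
        nv = new_df[c] if c in new_df else pd.Series(np.nan, index=full)
        out[c] = np.where(in_new, nv, p)
    return FPTable(full, full + step, out.reset_index(drop=True),
                   new.resolution_minutes, new.site_id or prior.site_id)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_data_qaqc(table: FPTable, site: SiteMetadata,
                  prior: Optional[FPTable] = None,
                  cfg: Optional[QCConfig] = None,
                  registry: Optional[VariableRegistry] = None,
                  prior_labels: Optional[Sequence[str]] = None) -> QAQCReport:
    """Execute all six data checks on the combined record and assemble the
    report.  Deterministic given (inputs, config)."""
    cfg = cfg or QCConfig()
    registry = registry or VariableRegistry.default()
    combined = combine_with_prior(table, prior)
    pot = potential_radiation(site, combined.start, combined.resolution_minutes)

    findings: list[Finding] = []
    _, f = timestamp_alignment(combined, site, cfg, pot=pot)
    findings += f
    findings += radiation_issue_check(combined, site, cfg, pot=pot)
    findings += physical_range_check(combined, registry, cfg=cfg, pot=pot)
    findings += variability_check(combined, cfg=cfg, registry=registry)
    findings += multivariate_check(combined, cfg=cfg)
    _, f = diurnal_seasonal_check(combined, site, cfg=cfg, pot=pot, registry=registry)
    findings += f
    _, f = ustar_filtering_check(combined, site, cfg=cfg, pot=pot)
    findings += f
    if prior_labels is None and prior is not None:
        prior_labels = prior.columns
    findings += variable_coverage_check(combined, prior_labels=prior_labels, cfg=cfg)

    digests = {"upload": table.digest()}
    if prior is not None:
        digests["prior"] = prior.digest()
    return assemble_report(findings, stage="DATA", site_id=site.site_id,
                           checks=DATA_CHECKS, config=cfg.to_dict(),
                           input_digests=digests)


#: single-check access used by targeted fault-recovery evaluations
CHECK_RUNNERS: dict[str, Callable] = {
    "timestamp_alignment": lambda t, s, c, r: timestamp_alignment(t, s, c)[1],
    "radiation": lambda t, s, c, r: radiation_issue_check(t, s, c),
    "physical_range": lambda t, s, c, r: physical_range_check(
        t, r, cfg=c, pot=potential_radiation(s, t.start, t.resolution_minutes)),
    "variability": lambda t, s, c, r: variability_check(t, cfg=c, registry=r),
    "multivariate": lambda t, s, c, r: multivariate_check(t, cfg=c),
    "diurnal_seasonal": lambda t, s, c, r: diurnal_seasonal_check(t, s, cfg=c,
                                                                  registry=r)[1],
    "ustar_filtering": lambda t, s, c, r: ustar_filtering_check(t, s, cfg=c)[1],
    "variable_coverage": lambda t, s, c, r: variable_coverage_check(t, cfg=c),
}


def run_single_check(name: str, table: FPTable, site: SiteMetadata,
                     cfg: Optional[QCConfig] = None,
                     registry: Optional[VariableRegistry] = None) -> list[Finding]:
    """Run one named check (see :data:`CHECK_RUNNERS`) and return findings."""
    cfg = cfg or QCConfig()
    registry = registry or VariableRegistry.default()
    return CHECK_RUNNERS[name](table, site, cfg, registry)
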