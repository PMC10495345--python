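"""Synthetic flux-met site records and fault injection.

The generator emulates a temperate mid-latitude site at half-hourly (or
hourly) resolution: clear-sky-index-scaled potential radiation, a seasonal
plus diurnal air-temperature cycle with AR(1) noise, a rectangular-
hyperbola light response with Q10 respiration for the CO2 flux (daytime
uptake negative), a Bowen-ratio energy partition, a diurnally modulated
lognormal friction velocity, and slowly varying soil states.  Every stream
draws from its own seeded substream, so adding a variable never perturbs
the others and two runs from the same seed are identical.

:func:`inject_fault` applies one declarative :class:`FaultSpec` — one per
issue in the data-check taxonomy — returning a new table that differs from
the clean twin only as the fault prescribes.  The shipped scenario catalog
(:data:`SCENARIOS`, used via :func:`make_fixture`) pairs each fault with
the check and finding code expected to fire, which is the oracle the
fault-recovery tests run against.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

from .fp_format import FPTable, SiteMetadata, make_time_axis
from .solar import potential_radiation

PPFD_PER_SW = 2.04  # umol photon per J shortwave, canonical conversion


@dataclass(frozen=True)
class SyntheticSiteConfig:
    """Study conditions for the synthetic site."""

    site: SiteMetadata = field(default_factory=lambda: SiteMetadata(
        site_id="XX-Syn", lat_deg=38.9, lon_deg=-92.2,
        utc_offset_hours=-6.0, igbp="DBF"))
    start: str = "2020-01-01"
    days: int = 366
    resolution_minutes: int = 30

    # radiation: clear-sky index with day-to-day AR(1) and intraday jitter
    clearness_mean: float = 0.72
    clearness_day_sigma: float = 0.12
    clearness_ar1: float = 0.6
    clearness_intraday_sigma: float = 0.04

    # air temperature (deg C)
    ta_mean: float = 12.0
    ta_seasonal_amp: float = 11.0
    ta_diurnal_amp: float = 4.0
    ta_ar1: float = 0.95
    ta_sigma: float = 0.8            # AR(1) innovation scale

    # CO2 flux light response and respiration
    fc_alpha: float = 0.10           # umol CO2 per W m-2 (initial slope)
    fc_pmax: float = 25.0            # umol m-2 s-1 plateau at peak season
    fc_pmax_winter_frac: float = 0.15
    fc_r0: float = 1.8               # base respiration at 10 degC
    fc_q10: float = 2.0
    fc_sigma: float = 1.5

    # energy partition
    bowen_ratio: float = 0.7
    energy_sigma: float = 20.0
    netrad_slope: float = 0.85
    netrad_offset: float = -55.0
    netrad_sigma: float = 15.0

    # turbulence
    ustar_night_median: float = 0.15  # m s-1
    ustar_day_median: float = 0.45
    ustar_sigma: float = 0.35        # lognormal AR(1) innovation scale
    ustar_ar1: float = 0.6
    ws_per_ustar: float = 7.5
    ws_offset: float = 0.4
    ws_lognoise: float = 0.05

    # other meteorology / soil
    ppfd_sigma: float = 15.0
    t_sonic_offset: float = 0.3
    t_sonic_sigma: float = 0.3
    rh_base: float = 0.8
    rh_sw_coef: float = 0.004
    rh_ar1: float = 0.9
    rh_sigma: float = 0.25
    swc_base: float = 28.0
    swc_seasonal_amp: float = 6.0    # wet spring / dry late summer cycle
    swc_ar1: float = 0.98
    swc_sigma: float = 0.25
    ts_lag_days: float = 20.0
    ts_seasonal_amp: float = 8.0
    ts_diurnal_amp: float = 1.0
    ts_ar1: float = 0.9
    ts_sigma: float = 0.3

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("clearness_day_sigma", "ta_sigma", "fc_sigma", "energy_sigma",
                     "ustar_sigma", "ppfd_sigma", "swc_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("clearness_ar1", "ta_ar1", "ustar_ar1", "rh_ar1",
                     "swc_ar1", "ts_ar1"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent substream per (seed, variable name)."""
    return np.random.default_rng(
        np.random.SeedSequence((seed & 0x7FFFFFFF, zlib.crc32(name.encode()))))


def _ar1(rng: np.random.Generator, n: int, phi: float, sigma: float) -> np.ndarray:
    eps = rng.normal(0.0, sigma, n)
    x = signal.lfilter([1.0], [1.0, -phi], eps)
    if phi > 0:  # start near stationarity
        x[0] = rng.normal(0.0, sigma / np.sqrt(1 - phi * phi))
        x = signal.lfilter([1.0], [1.0, -phi], eps, zi=[phi * x[0]])[0]
    return x


def generate_clean(config: Optional[SyntheticSiteConfig] = None) -> FPTable:
    """Generate one clean synthetic flux-met record (passes all checks)."""
    cfg = config or SyntheticSiteConfig()
    ipd = 24 * 60 // cfg.resolution_minutes
    n = cfg.days * ipd
    start, end = make_time_axis(cfg.start, n, cfg.resolution_minutes)
    pot = potential_radiation(cfg.site, start, cfg.resolution_minutes)
    doy = start.dayofyear.to_numpy().astype(float)
    hour = start.hour.to_numpy() + start.minute.to_numpy() / 60.0
    seed = cfg.seed

    # --- radiation ---------------------------------------------------------
    rng = _stream(seed, "clearness")
    day_anom = _ar1(rng, cfg.days, cfg.clearness_ar1, cfg.clearness_day_sigma)
    intraday = _ar1(rng, n, 0.8, cfg.clearness_intraday_sigma)
    clearness = np.clip(cfg.clearness_mean + np.repeat(day_anom, ipd) + intraday,
                        0.05, 0.95)
    sw_in = clearness * pot
    ppfd = PPFD_PER_SW * sw_in + _stream(seed, "ppfd").normal(0, cfg.ppfd_sigma, n)
    netrad = (cfg.netrad_slope * sw_in + cfg.netrad_offset
              + _stream(seed, "netrad").normal(0, cfg.netrad_sigma, n))

    # --- temperature -------------------------------------------------------
    seasonal_phase = 2 * np.pi * (doy - 196) / 365.25  # warmest ~mid July
    diurnal_phase = 2 * np.pi * (hour - 14.0) / 24.0   # warmest ~14:00
    hemis = 1.0 if cfg.site.lat_deg >= 0 else -1.0
    ta = (cfg.ta_mean + hemis * cfg.ta_seasonal_amp * np.cos(seasonal_phase)
          + cfg.ta_diurnal_amp * np.cos(diurnal_phase)
          + _ar1(_stream(seed, "ta"), n, cfg.ta_ar1, cfg.ta_sigma))
    t_sonic = (ta + cfg.t_sonic_offset
               + _stream(seed, "t_sonic").normal(0, cfg.t_sonic_sigma, n))

    # --- CO2 flux: light response + Q10 respiration ------------------------
    season = (1 + cfg.fc_pmax_winter_frac) / 2 \
        + (1 - cfg.fc_pmax_winter_frac) / 2 * hemis * np.cos(seasonal_phase)
    pmax = cfg.fc_pmax * season
    gpp = cfg.fc_alpha * sw_in * pmax / (cfg.fc_alpha * sw_in + pmax)
    reco = cfg.fc_r0 * cfg.fc_q10 ** ((ta - 10.0) / 10.0)
    fc = -gpp + reco + _stream(seed, "fc").normal(0, cfg.fc_sigma, n)

    # --- energy partition ---------------------------------------------------
    available = np.maximum(netrad, 0.0)
    le = (available / (1 + cfg.bowen_ratio)
          + _stream(seed, "le").normal(0, cfg.energy_sigma, n))
    h = (available * cfg.bowen_ratio / (1 + cfg.bowen_ratio)
         + _stream(seed, "h").normal(0, cfg.energy_sigma, n))

    # --- turbulence ---------------------------------------------------------
    pot_max = pot.max() if pot.max() > 0 else 1.0
    daylight = np.clip(pot / pot_max, 0.0, 1.0) ** 0.5
    log_med = (np.log(cfg.ustar_night_median)
               + (np.log(cfg.ustar_day_median) - np.log(cfg.ustar_night_median))
               * daylight)
    ustar = np.exp(log_med + _ar1(_stream(seed, "ustar"), n, cfg.ustar_ar1,
                                  cfg.ustar_sigma))
    ws = ((cfg.ws_offset + cfg.ws_per_ustar * ustar)
          * np.exp(_stream(seed, "ws").normal(0, cfg.ws_lognoise, n)))

    # --- humidity and soil ---------------------------------------------------
    z = (cfg.rh_base - cfg.rh_sw_coef * sw_in
         + _ar1(_stream(seed, "rh"), n, cfg.rh_ar1, cfg.rh_sigma))
    rh = 5.0 + 94.0 / (1.0 + np.exp(-z))
    swc_phase = 2 * np.pi * (doy - 105) / 365.25  # wettest mid spring
    swc = (cfg.swc_base + cfg.swc_seasonal_amp * np.cos(swc_phase)
           + _ar1(_stream(seed, "swc"), n, cfg.swc_ar1, cfg.swc_sigma))
    ts_phase = 2 * np.pi * (doy - 196 - cfg.ts_lag_days) / 365.25
    ts = (cfg.ta_mean + hemis * cfg.ts_seasonal_amp * np.cos(ts_phase)
          + cfg.ts_diurnal_amp * np.cos(diurnal_phase)
          + _ar1(_stream(seed, "ts"), n, cfg.ts_ar1, cfg.ts_sigma))

    data = pd.DataFrame({
        "FC": fc, "LE": le, "H": h, "NETRAD": netrad, "SW_IN": sw_in,
        "PPFD_IN": ppfd, "TA": ta, "T_SONIC": t_sonic, "RH": rh, "WS": ws,
        "USTAR": ustar, "SWC_1_1_1": swc, "TS_1_1_1": ts,
    })
    return FPTable(start, end, data, cfg.resolution_minutes, cfg.site.site_id)


# ---------------------------------------------------------------------------
# fault injection
# ---------------------------------------------------------------------------

FAULT_KINDS = (
    "TIMESTAMP_SHIFT", "DST", "SIGN_FLIP", "UNIT_RATIO", "CONSTANT_FILL",
    "STEP_CHANGE", "DRIFT", "CUTOFF", "OUTLIERS", "USTAR_FILTER", "GAP",
    "DROP_VARIABLE", "ROW_SKIP",
)


@dataclass(frozen=True)
class FaultSpec:
    """Declarative description of one defect to inject.

    ``magnitude`` is the kind-specific scalar: shift intervals, unit
    factor, fill value, step delta, drift rate per year, cut-off bound, or
    u* threshold.  ``span`` is a (start, end) pair of ``YYYYMMDDHHMM``
    strings, start-inclusive, end-exclusive.
    """

    kind: str
    var: Optional[str] = None
    span: Optional[tuple[str, str]] = None
    magnitude: Optional[float] = None
    rate: Optional[float] = None     # OUTLIERS: fraction of points
    scale: Optional[float] = None    # OUTLIERS: spike amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FAULT_KINDS:
            raise ValueError(f"unknown fault kind {self.kind!r}")


def _span_mask(table: FPTable, span: tuple[str, str]) -> np.ndarray:
    t0 = pd.Timestamp(pd.to_datetime(span[0], format="%Y%m%d%H%M"))
    t1 = pd.Timestamp(pd.to_datetime(span[1], format="%Y%m%d%H%M"))
    return (table.start >= t0) & (table.start < t1)


def _shift_rows(data: pd.DataFrame, rows: np.ndarray, k: int) -> pd.DataFrame:
    """Displace the values in `rows` by k rows relative to the time axis."""
    out = data.copy()
    idx = np.flatnonzero(rows) if rows.dtype == bool else rows
    src = idx - k
    valid = (src >= 0) & (src < len(data))
    vals = data.to_numpy()
    new = vals.copy()
    new[idx[valid]] = vals[src[valid]]
    new[idx[~valid]] = np.nan
    out.iloc[:, :] = new
    return out


def inject_fault(table: FPTable, fault: FaultSpec) -> FPTable:
    """Return a new table differing from the input only as the fault
    prescribes; the input (clean twin) is never modified."""
    t = table.copy()
    kind = fault.kind

    if kind in ("SIGN_FLIP", "UNIT_RATIO", "CONSTANT_FILL", "STEP_CHANGE",
                "DRIFT", "CUTOFF", "OUTLIERS", "GAP", "DROP_VARIABLE"):
        if fault.var not in t.data.columns:
            raise ValueError(f"fault references absent variable {fault.var!r}")

    if kind == "TIMESTAMP_SHIFT":
        k = int(fault.magnitude)
        t.data = _shift_rows(t.data, np.ones(len(t), dtype=bool), k)
    elif kind == "DST":
        if fault.span is None:
            raise ValueError("DST fault needs a span")
        k = 60 // t.resolution_minutes  # clocks ahead one hour
        t.data = _shift_rows(t.data, _span_mask(t, fault.span), k)
    elif kind == "SIGN_FLIP":
        t[fault.var] = -t[fault.var]
    elif kind == "UNIT_RATIO":
        t[fault.var] = t[fault.var] * float(fault.magnitude)
    elif kind == "CONSTANT_FILL":
        m = _span_mask(t, fault.span)
        x = t[fault.var]
        x[m] = float(fault.magnitude)
        t[fault.var] = x
    elif kind == "STEP_CHANGE":
        m = t.start >= pd.Timestamp(pd.to_datetime(fault.span[0],
                                                   format="%Y%m%d%H%M"))
        x = t[fault.var]
        x[m] = x[m] + float(fault.magnitude)
        t[fault.var] = x
    elif kind == "DRIFT":
        years = (t.start.asi8 - t.start.asi8[0]) / (365.25 * 24 * 3600 * 10**9)
        t[fault.var] = t[fault.var] + float(fault.magnitude) * years
    elif kind == "CUTOFF":
        t[fault.var] = np.minimum(t[fault.var], float(fault.magnitude))
    elif kind == "OUTLIERS":
        rng = _stream(fault.seed, f"outliers:{fault.var}")
        x = t[fault.var]
        hit = rng.random(len(x)) < float(fault.rate)
        signs = rng.choice([-1.0, 1.0], size=len(x))
        x = np.where(hit & np.isfinite(x), x + signs * float(fault.scale), x)
        t[fault.var] = x
    elif kind == "USTAR_FILTER":
        if "USTAR" not in t.data.columns or "FC" not in t.data.columns:
            raise ValueError("USTAR_FILTER needs USTAR and FC columns")
        night = t["SW_IN"] <= 0.0 if "SW_IN" in t.data.columns \
            else np.ones(len(t), dtype=bool)
        x = t["FC"]
        x[night & (t["USTAR"] < float(fault.magnitude))] = np.nan
        t["FC"] = x
    elif kind == "GAP":
        m = _span_mask(t, fault.span)
        x = t[fault.var]
        x[m] = np.nan
        t[fault.var] = x
    elif kind == "DROP_VARIABLE":
        t.data = t.data.drop(columns=[fault.var])
    elif kind == "ROW_SKIP":
        keep = ~_span_mask(t, fault.span)
        t = FPTable(t.start[keep], t.end[keep], t.data.iloc[keep],
                    t.resolution_minutes, t.site_id)
    return t


def inject_faults(table: FPTable, faults: list[FaultSpec]) -> FPTable:
    for f in faults:
        table = inject_fault(table, f)
    return table


# ---------------------------------------------------------------------------
# scenario catalog: fault -> expected check and finding code
# ---------------------------------------------------------------------------

def _mad(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    return float(np.median(np.abs(x - np.median(x))))


def scenario_faults(name: str, clean: FPTable, seed: int) -> list[FaultSpec]:
    """Fault list for a named scenario, parameterized on the clean twin."""
    year = clean.start[0].year
    mid = f"{year}07010000"
    if name == "clean":
        return []
    if name == "timestamp_shift":
        return [FaultSpec("TIMESTAMP_SHIFT", magnitude=2)]
    if name == "dst":
        return [FaultSpec("DST", span=(f"{year}03080200", f"{year}11010200"))]
    if name == "sign_flip":
        return [FaultSpec("SIGN_FLIP", var="FC")]
    if name == "unit_ratio_sw":
        return [FaultSpec("UNIT_RATIO", var="SW_IN", magnitude=2.0)]
    if name == "percent_ratio_rh":
        return [FaultSpec("UNIT_RATIO", var="RH", magnitude=0.01)]
    if name == "constant_fill":
        return [FaultSpec("CONSTANT_FILL", var="TA", magnitude=12.34,
                          span=(f"{year}05100000", f"{year}05130000"))]
    if name == "step_change":
        delta = 3.0 * _mad(clean["SWC_1_1_1"])
        return [FaultSpec("STEP_CHANGE", var="SWC_1_1_1", magnitude=delta,
                          span=(mid, mid))]
    if name == "drift":
        return [FaultSpec("DRIFT", var="SWC_1_1_1", magnitude=8.0)]
    if name == "cutoff":
        bound = float(np.nanquantile(clean["WS"], 0.85))
        return [FaultSpec("CUTOFF", var="WS", magnitude=bound)]
    if name == "outliers":
        scale = 12.0 * _mad(clean["TA"])
        return [FaultSpec("OUTLIERS", var="TA", rate=0.02, scale=scale, seed=seed)]
    if name == "ustar_filter":
        return [FaultSpec("USTAR_FILTER", magnitude=0.25)]
    if name == "long_gap":
        return [FaultSpec("GAP", var="SWC_1_1_1",
                          span=(f"{year}06010000", f"{year}08300000"))]
    if name == "drop_mandatory":
        return [FaultSpec("DROP_VARIABLE", var="FC")]
    if name == "row_skip":
        return [FaultSpec("ROW_SKIP", span=(f"{year}04150000", f"{year}04150300"))]
    raise KeyError(f"unknown scenario {name!r}")


#: scenario -> (check to run, finding codes expected to fire)
SCENARIOS: dict[str, tuple[str, tuple[str, ...]]] = {
    "clean": ("", ()),
    "timestamp_shift": ("timestamp_alignment", ("TIMESTAMP_SHIFT",)),
    "dst": ("timestamp_alignment", ("DST",)),
    "sign_flip": ("diurnal_seasonal", ("SIGN_FLIP",)),
    "unit_ratio_sw": ("radiation", ("HIGH_RADIATION",)),
    "percent_ratio_rh": ("physical_range", ("PERCENT_AS_RATIO",)),
    "constant_fill": ("variability", ("FILLED_CONSTANT",)),
    "step_change": ("variability", ("STEP_CHANGE",)),
    "drift": ("variability", ("TREND",)),
    "cutoff": ("variability", ("CUTOFF",)),
    "outliers": ("physical_range", ("EXCESSIVE_OUTLIERS",)),
    "ustar_filter": ("ustar_filtering", ("FC_FILTERED",)),
    "long_gap": ("variable_coverage", ("LONG_GAP",)),
    "drop_mandatory": ("variable_coverage", ("MISSING_MANDATORY",)),
    "row_skip": ("format", ("SKIPPED_INTERVALS",)),
}


def make_fixture(name: str, seed: int = 0,
                 config: Optional[SyntheticSiteConfig] = None
                 ) -> tuple[FPTable, tuple[str, tuple[str, ...]]]:
    """Deterministic fixture: faulted table plus its (check, codes) oracle."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}")
    cfg = config or SyntheticSiteConfig()
    cfg = replace(cfg, seed=seed)
    clean = generate_clean(cfg)
    faults = scenario_faults(name, clean, seed)
    table = inject_faults(clean, faults)
    return table, SCENARIOS[name]
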