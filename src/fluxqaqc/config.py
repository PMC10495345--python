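"""Thresholds configuration for the data checks.

Every numeric knob of the six data checks lives here with its default, so a
reviewer can retune any detector without touching code.  Values can be
overridden from a YAML mapping (only known keys are accepted).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path
from typing import Union

import yaml


@dataclass
class QCConfig:
    # -- timestamp alignment ------------------------------------------------
    window_days: int = 15            # sliding-window length for lag estimation
    window_step_days: int = 5
    max_lag: int = 10                # search range, intervals
    min_coverage: float = 0.5        # min fraction of usable daytime samples per window
    lag_r_min: float = 0.8           # min peak correlation for a window to vote
    lag_fraction: float = 0.8        # fraction of windows agreeing => constant-lag finding
    dst_min_plateau: int = 4         # min windows per plateau for the DST signature

    # -- radiation issues ---------------------------------------------------
    headroom: float = 1.05           # SW_IN may exceed SW_IN_POT by this factor
    pot_floor: float = 50.0          # W m-2; daytime mask for ratio statistics
    excess_frac: float = 0.02        # tolerated fraction of above-ceiling daytime points
    asym_tol: float = 0.10           # |median am - pm| clearness asymmetry => tilt
    tilt_min_months: int = 3
    shade_tol: float = 0.6           # sector ratio below shade_tol * monthly median
    shade_min_bins: int = 3
    shade_min_months: int = 2

    # -- physical range -----------------------------------------------------
    outlier_k: float = 6.0           # plausible range = seasonal median +/- k * MAD
    outlier_frac: float = 0.01       # tolerated fraction outside the plausible range
    percent_max: float = 1.5         # percent variable with max below this => ratio units
    n_min: int = 100                 # min non-missing values for distributional checks

    # -- variability --------------------------------------------------------
    trend_tol: float = 4.0           # |slope * record length| in robust-sigma units
    trend_t_tol: float = 6.0         # t-statistic gate for the linear coefficient
    step_tol: float = 7.0            # sup-t of a fitted step vs harmonic background
    step_min_seg_days: int = 20
    run_min: int = 48                # intervals of identical values => filled constant
    cutoff_frac: float = 0.005       # tolerated probability mass at an interior extreme

    # -- multivariate comparison -------------------------------------------
    mv_window_days: int = 30
    mv_min_pts: int = 200            # min joint samples per window
    mv_subsample: int = 400          # cap on points entering the Theil-Sen fit
    mv_outlier_k: float = 6.0
    mv_outlier_frac: float = 0.01
    mv_bias_tol: float = 3.0         # daily median residual in global-sigma units
    mismatch_min_days: int = 5       # consecutive biased days => short-term mismatch
    r2_perfect: float = 0.9999
    mv_drift_tol: float = 0.15       # relative drift of the windowed slope
    mv_step_tol: float = 0.15        # relative step in the windowed slope

    # -- diurnal-seasonal pattern -------------------------------------------
    sign_margin: float = 1.0         # umol m-2 s-1; day-night composite margin
    growing_amp_frac: float = 0.25   # month counts as growing season above this
    sign_min_frac: float = 0.5       # fraction of growing months flagged => sign flip
    composite_lag_bins: int = 6
    composite_lag_frac: float = 0.67
    yoy_step_tol: float = 6.0        # year-over-year composite displacement, MAD units
    min_months: int = 3

    # -- USTAR filtering ----------------------------------------------------
    ustar_bin_width: float = 0.05    # m s-1
    ustar_max: float = 1.0
    ustar_bin_min_count: int = 10
    low_avail: float = 0.1
    high_avail: float = 0.5
    ustar_floor: float = 0.1         # m s-1; nighttime 1st percentile above => truncated
    n_night: int = 200

    # -- variable coverage --------------------------------------------------
    gap_tol_days: int = 60

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "QCConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "QCConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
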