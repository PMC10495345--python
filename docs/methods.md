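# Methods

This note documents the models, detectors and numerical choices behind
`fluxqaqc`: what each component assumes, which knobs matter, what the
synthetic generator does and does not emulate, and the limitations a user
should keep in mind when transferring conclusions from synthetic tests to
real tower records.

## Scope and data model

The toolkit operates on half-hourly or hourly flux-met tables: paired
`TIMESTAMP_START`/`TIMESTAMP_END` columns (`YYYYMMDDHHMM`, local standard
time, never daylight-saving time) plus numeric variables named by the
flux-processing convention (base, optional general qualifiers from
{PI, F, QC, SD, N}, optional `_H_V_R` positional triple). Missing values
are `-9999` on disk and NaN in memory; no numeric `-9999` survives a read,
and `-9999` is the only serialized missing form. The writer emits the
shortest decimal representation that reparses to the identical double, so
`read -> write -> read` is a bit-stable fixed point after the first write.
Parsed cells are re-converted with the correctly rounded scalar parser
because the fast vectorized path in the CSV stack can be one ulp off,
which would silently break that contract.

The variable registry ships ~58 common bases with units and *hard*
physical limits (generous, physically impossible bounds — not
plausibility bounds). It is user-extensible; lookups never guess: an
unknown base is a value (`None`), not an error.

## Format QA/QC

Format assessment runs read → check → one autocorrection pass → re-check.
The status algebra is strict: `PASS` iff no findings, `FIXED` iff every
finding was fixed, `FAIL` otherwise. The fixable set is closed and
typographic only: filling skipped intervals with missing rows, case-fold
renames against the registry (`fc_1_1_1 -> FC_1_1_1`; never semantic
renames such as `NEE -> FC`, and never when two labels would collide),
recomputing `TIMESTAMP_END` from the start axis, sorting a non-monotonic
but duplicate-free axis, and delimiter normalization. Autocorrection is
conservative (every input cell value survives identically) and idempotent.
Duplicate timestamps and unparseable timestamps are never fixed —
guessing would risk data corruption. A filename outside the
`SITEID_RES_START_END.csv` convention is recorded and "fixed" by noting
the canonical name, so a filename alone cannot fail a submission.

## Solar reference

All timing and ceiling checks rest on top-of-atmosphere potential
shortwave, `SW_IN_POT = S0 · E0(doy) · max(cos θ, 0)` with `S0 = 1361
W m⁻²`. Declination and the equation of time come from the Astronomical
Almanac low-precision solar ephemeris (~0.01° accuracy against an
independently coded NOAA oracle); the eccentricity factor `E0` uses
Spencer's series (its ~10⁻⁴ accuracy is irrelevant at a 5% radiation
headroom). Two properties are load-bearing and tested exactly:

* **translation** — potential radiation is a pointwise function of the
  interval-midpoint instant, so lag-shifting the time axis shifts the
  series identically; the cross-correlation lag estimator inherits its
  exactness from this;
* **midpoint evaluation** — evaluating at interval midpoints makes a
  beginning-vs-ending timestamp confusion appear as exactly a ±1-interval
  lag rather than a half-step smear.

"Night" is everywhere defined as `SW_IN_POT == 0` (computed, not
measured), so a broken radiation sensor cannot corrupt the day/night
split used by other checks.

## The six data checks

**Timestamp alignment.** Measured `SW_IN` (fallback `PPFD_IN`) is
cross-correlated against `SW_IN_POT` in 15-day windows stepped by 5 days,
over integer lags ±10 intervals; a window votes when its daytime coverage
is ≥ 50% and peak Pearson correlation ≥ 0.8 (correlation is scale-free,
so amplitude faults do not corrupt timing). The lag pattern is then
classified: two season-long plateaus separated by one hour → daylight
saving; a persistent ±1 lag → beginning/ending convention; any other
constant nonzero lag → timestamp shift (flagged as a possible time-zone
mismatch when it is a whole number of hours); `SW_IN` and `PPFD_IN`
disagreeing on their modal lag → streams not synchronized.

**Radiation issues** (same module family): fraction of daytime intervals
above `1.05 × SW_IN_POT` beyond 2% → excess radiation; a persistent
(≥ 3 months) morning/afternoon asymmetry of the clearness ratio beyond
0.10 → tilted sensor; a contiguous time-of-day sector (≥ 3 half-hour
bins, ≥ 2 months) with clearness below 0.6 of the monthly daytime median
→ shading.

**Physical range.** Hard-limit violations come straight from the
registry. Plausible ranges are site-specific: median ± 6·MAD per
variable, per meteorological quarter, per computed day/night class, with
*asymmetric* spread (separate MAD of deviations above and below the
median) and clipping to the hard limits. The stratification and the
asymmetry are both necessary: pooled two-sided MAD bounds flag several
percent of perfectly clean values for any skewed diurnal quantity
(radiation, friction velocity, energy fluxes). A finding requires > 1% of
values outside the bounds. Percent-kind variables (RH, SWC) whose maximum
is ≤ 1.5 over ≥ 100 values are reported as ratio-units submissions.

**Variability** (grouped under physical range): runs of ≥ 48 identical
consecutive values → filled constant; probability mass > 0.5% piled at an
interior extreme (excluding extremes that coincide with a hard limit,
which are physical saturation, and excluding exact zero for radiation,
which is night) → cut-off. Trend and step operate on daily medians of
slowly varying state variables (meteorology, soil, concentration kinds
only — radiation- and flux-kind drift is screened against reference
signals by the multivariate and radiation checks, because a harmonic
background is misspecified for clearness-driven series). The background
model is `[1, t, sin, cos, sin2, cos2]` (annual + semiannual). A trend
fires when the linear coefficient is both statistically solid (t ≥ 6,
with the standard error taken from the joint fit so that the
linear/harmonic collinearity of partial-year records automatically
deflates it) and material (|slope × span| > 4 robust σ of the daily
residuals). A step is found by a sup-t scan: at each candidate breakpoint
(≥ 20 days from either end) a step term is fitted *jointly* with the
background, and the maximum |t| is compared against 7.0 — a threshold
calibrated so that the clean-twin null (max sup-t ≈ 5.6 across 20 seeds ×
6 variables) stays silent while a 3·MAD step scores ≈ 40. Fitting the
step jointly matters: scanning residuals of a background-only fit lets
the harmonics absorb most of a mid-year step.

**Multivariate comparison.** Default pairs: `PPFD_IN~SW_IN`,
`WS~USTAR`, `T_SONIC~TA`, `NETRAD~SW_IN`. The global fit is a Theil–Sen
slope (deterministically subsampled to ≤ 400 points) with the intercept
taken as `median(y − slope·x)` over all points — the textbook
`median(y) − slope·median(x)` decomposition is biased when x is bimodal,
as radiation is with its night cluster at zero. Residual outliers are
flagged against a residual MAD *conditional on x* (deciles), so
multiplicative noise (wind/friction velocity) does not masquerade as
outliers; a finding requires > 1% beyond 6·MAD. Short-term mismatch is a
run of ≥ 5 consecutive days whose median residual (over the informative
upper half of the x range) exceeds 3 robust σ. R² > 0.9999 over the
joint record → one variable derived from the other. Thirty-day windowed
Theil–Sen slopes feed the slope-drift (relative drift > 15%) and
slope-step (relative two-segment step > 15%) screens.

**Diurnal-seasonal pattern.** Median diurnal composites (median, IQR,
count per time-of-day bin per month; bin counts conserve the number of
non-missing values). Growing-season months are defined internally as
months whose day/night composite amplitude reaches 25% of the annual
maximum — no external phenology input. A sign-convention flip is declared
when, in at least half of the growing months, the daytime composite
median exceeds the nighttime one by > 1 µmol m⁻² s⁻¹ *and* the composite
correlates positively with the potential-radiation composite (uptake
should anti-correlate). The monthly composite lag against the potential
composite corroborates the alignment check at monthly resolution;
composite medians outside hard limits and year-over-year composite
displacement (≥ 2 years of data) complete the module.

**USTAR filtering.** Nighttime u* is binned at 0.05 m s⁻¹; bins need
≥ 10 samples to vote. FC-filtering is declared when every bin below some
edge has FC availability < 0.1 while pooled availability above is ≥ 0.5;
the reported threshold is the highest such edge, which recovers injected
thresholds on bin-edge values exactly and any threshold within one bin
width. A truncated u* record (deleted low-turbulence rows) is declared
when the nighttime 1st percentile sits above 0.1 m s⁻¹.

**Variable coverage.** Interior gaps (leading/trailing missing spans are
ignored, which also makes every check invariant to padding the record
with fully-missing rows) longer than 60 days; all-empty columns; the
mandatory carbon flux re-asserted on the combined record; and label-set
differences against the previously published record.

Uploads are combined with the prior published record by row-wise
replacement: rows whose start timestamp falls in the upload's axis come
entirely from the upload, the label set is the union. Severity follows a
fixed rule — hard-limit violations, sign flips, timestamp shifts (DST and
begin/end confusion included) and percent-as-ratio are `ACTION_REQUIRED`;
everything else defaults to `WARNING`; a check that cannot run is
`SKIPPED` (neither pass nor fail). The overall report status is the
maximum severity, with ordering PASS < SKIPPED < WARNING <
ACTION_REQUIRED. JSON is the canonical report form (deterministic:
sorted keys, no wall-clock content, config snapshot and input digests
embedded); the text rendering is derived from it.

## Synthetic site generator

The generator emulates one temperate, mid-latitude deciduous site
(default: 38.9° N, 92.2° W, UTC−6) for one leap year at 30 minutes. Its
streams:

* `SW_IN = clearness × SW_IN_POT`, clearness = 0.72 mean with day-to-day
  AR(1) (σ 0.12, φ 0.6) plus intraday jitter, clipped to [0.05, 0.95] so
  clean radiation never exceeds the potential ceiling;
* `PPFD_IN = 2.04 × SW_IN + N(0, 15)` — the canonical µmol J⁻¹
  conversion, so the default multivariate pair has a known slope;
* `TA`: 12 °C mean, 11 °C seasonal and 4 °C diurnal sinusoids, AR(1)
  noise (φ 0.95); `T_SONIC = TA + 0.3 + N(0, 0.3)`;
* `FC`: rectangular-hyperbola light response (α = 0.10 µmol W⁻¹ m⁻² s⁻¹,
  Pmax 25 µmol m⁻² s⁻¹ with a seasonal envelope down to 15% in winter)
  minus sign, plus Q10 respiration (R0 1.8, Q10 2.0) and N(0, 1.5) —
  daytime growing-season uptake negative, nighttime respiration positive;
* energy: `NETRAD = 0.85·SW_IN − 55 + N(0, 15)`; LE and H partition
  positive net radiation by a Bowen ratio of 0.7 with N(0, 20) noise;
* turbulence: lognormal u* (nighttime median 0.15, daytime 0.45 m s⁻¹,
  AR(1) log-noise), `WS = (0.4 + 7.5·USTAR)·lognormal(0.05)`;
* `RH` through a logistic squash into (5, 99) % (no mass at the bounds);
  `SWC` with a 6% seasonal wet/dry cycle plus slow AR(1); `TS` as a
  lagged, damped TA.

Every stream draws from its own `(seed, name)` substream, so adding a
variable never perturbs existing ones and records are reproducible from a
single seed. The per-stream noise scales were chosen once for realism;
two interact with detector margins and are worth noting: u* uses a
moderate lognormal spread (ln-σ ≈ 0.44 — a heavier tail is possible at
real sites and would require a larger outlier `k`), and SWC carries a
seasonal cycle because a purely autoregressive soil-moisture series has
MAD ≈ its day-scale noise, which makes "a 3·MAD step" an artificially
marginal event rather than the clearly visible sensor fault it is in real
records.

Faults are declarative (`FaultSpec`): timestamp shift, DST span, sign
flip, unit ratio, constant fill, step, drift, cut-off, outlier spikes,
u* filtering, long gap, dropped variable, skipped rows — thirteen kinds,
each mapping to exactly one designated check and finding code in the
shipped scenario catalog (the fault → check oracle used by the
fault-recovery tests). Faulted tables differ from their clean twin only
as the fault prescribes.

What the generator does **not** emulate: precipitation and intermittent
processes (rain events, snow), multi-year climate trends, instrument
noise nonstationarity, real gap patterns (it generates complete records;
gaps are injected), energy-balance non-closure, advection, and
high-latitude photoperiods (above ~55° the winter night exceeds the
48-interval constant-run threshold and the night-zero radiation run would
need a latitude-aware `run_min`). Passing the fault matrix therefore
demonstrates that each detector responds to its target signature at
realistic amplitude and is silent on a realistic clean record — not that
thresholds are tuned for every ecosystem; they are all overridable in one
YAML config for that reason.

## Wavelet spectra

The global spectrum is a continuous Morlet transform (ω₀ = 6) evaluated
in the Fourier domain on log₂-spaced scales (4 per octave) from 2
intervals to a quarter of the record, time-averaged and divided by scale.
The wavelet normalization is chosen so that the *rectified* spectrum of
white noise is flat in expectation — the spectrum reads as variance per
unit scale, and equal-variance processes are comparable across periods.
Missing values are zeroed after robust standardization (median/MAD), the
simplest gap treatment that adds no energy and biases no location; the
output is rescaled to physical variance units, so scaling a series by c
scales power by c² to machine precision. A series is analyzed only when
more than 25% of it is present; the refusal carries the measured
coverage. Periods beyond a quarter of the record are excluded (cone of
influence); resolving an annual peak therefore needs ≥ 4 years of data.

## Problem sizes and determinism

The shipped tests and the acceptance script size their simulations as:
one synthetic year (17,568 half-hours) per fault-matrix cell, 20 seeds
for the sensitivity/false-alarm matrix, 1,000 fuzzed files for the format
round trip, 1,000 random site-instants for the solar oracle, 50 noise
seeds for spectral flatness, and 2–4 synthetic years for spectral peak
location. Everything downstream of a seed is deterministic: checks use
no randomness (robust fits subsample on a fixed stride), reports contain
no wall-clock content, and identical inputs produce byte-identical JSON.
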