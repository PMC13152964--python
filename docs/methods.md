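# Methods

## The problem and the method

Heat stress degrades the welfare and productivity of beef cattle, and its
geographic footprint is expected to grow with climate warming.  `heatload`
implements a projection pipeline that turns daily gridded climate variables
into seasonal maps of cattle thermal-welfare categories and land-area
exposure statistics:

1. **Quality control** of the four daily input variables — near-surface air
   temperature (K), relative humidity (%), downwelling shortwave radiation
   (W/m²), wind speed (m/s) — on a regular 0.25° lat–lon grid: missing-data
   sentinels (|v| ≥ 10¹⁹, guarding the conventional 10²⁰ marker against
   single-precision round-off) become missing; negative wind and radiation
   are set to zero; humidity is clamped into [0, 100]; temperatures at or
   below 0 K become missing (excluded, not clamped).  A terrestrial mask
   removes ocean cells.
2. **Seasonal climatology per model**: arithmetic mean of all non-missing
   days whose month falls in a meteorological season (DJF, MAM, JJA, SON)
   and whose calendar year falls in a named period.  Built-in periods are
   the 30-year climatological normal (CliNo, 1985–2014) and three 25-year
   projection windows (2026–2050, 2051–2075, 2076–2100).  A cell whose
   fraction of contributing days falls below `min_coverage` (default 0.9)
   is missing rather than biased.
3. **Multi-model ensemble (MME)**: equal-weighted mean across models, per
   cell and variable, skipping models that are missing at a cell.
4. **Heat-Load Index** from the ensemble-mean climate.  Black-globe
   temperature (°C) is estimated from air temperature Ta (°C) and shortwave
   radiation SR (W/m²),

       BGT = 1.33·Ta − 2.65·√Ta + 3.21·log₁₀(SR + 1) + 3.5,

   and the HLI is the two-branch formula switched on BGT:

       BGT <  25:  HLI = 10.66 + 0.28·RH + 1.3·BGT − WS
       BGT ≥  25:  HLI =  8.62 + 0.38·RH + 1.55·BGT − 0.5·WS + e^(2.4 − WS)

5. **Classification** of the seasonal-mean HLI into the five welfare bands
   calibrated on feedlot panting scores: Comfort (≤ 70), Mild (70–77],
   Moderate (77–86], Severe (86–96], Extreme (> 96].  Boundary values
   belong to the lower band.
6. **Exposure accounting**: cell areas from the spherical-zone formula
   A = R²·Δλ·(sin φ₊ − sin φ₋) with R = 6371 km; the exposure statistic is
   the percentage of land area in the Extreme band, globally and per
   country (cells assigned by cell-center containment in country polygons);
   changes are signed percentage-point (pp) differences from the baseline.

## Design choices where the method was genuinely open

- **Aggregation order.** The index is computed from the ensemble-mean
  seasonal climate (mean-climate-then-index), not per model and then
  averaged.  The alternative (index-then-mean) is available by calling
  `hli_from_climatology` on per-model climatologies and averaging, but is
  deliberately not the default.
- **DJF year convention.** December is grouped with January/February of the
  *same* calendar year.  Over 25–30-year windows the two conventions differ
  by one month in ~90, i.e. negligibly; the spanning convention
  (`djf_spanning=True`) is provided for sensitivity work.
- **Climatological mean.** Seasonal means are the joint mean of daily
  values over all years of the period (not the mean of per-year means);
  the two coincide whenever every year contributes the same day count.
- **Branch boundary.** The upper HLI branch applies at BGT ≥ 25 °C exactly.
  The two branches do not meet at the boundary (the jump is ≈ 3.7 HLI units
  at RH = 50, WS = 2); no smoothing is applied, and the test suite
  documents the discontinuity.
- **Sub-zero air temperature.** √Ta is undefined below 0 °C, outside the
  empirical BGT calibration domain.  Cells with seasonal-mean Ta < 0 °C are
  assigned Comfort directly (they cannot approach the first threshold at
  70), with BGT and HLI recorded missing; `subzero="missing"` leaves them
  unclassified instead.
- **Calendars.** Standard, no-leap and 360-day model calendars are
  supported; each model's own calendar selects its days and every selected
  day is weighted equally.  No re-calendaring is performed.
- **Region assignment.** Cell-center containment, first polygon wins on
  overlap.  This is deterministic and matches 0.25° granularity, but
  misassigns coastal slivers relative to area-weighted splitting.
- **Denominators.** A country's share uses its own land area; the global
  share uses all land cells of the grid (a real archive's grid stops at
  60°S, excluding Antarctica by construction).
- **Rounding.** Shares are kept at full precision internally; round to one
  decimal only at presentation time.

## The synthetic archive and what it does (not) show

`synthetic.generate_archive` writes a miniature archive in the same
CF-convention NetCDF layout the reader consumes.  Each variable is a
deterministic signal — a latitudinal/longitudinal mean gradient, a seasonal
cosine whose peak day flips by half a year across the equator, a
per-scenario linear warming trend on air temperature (°C/decade against the
baseline midpoint), small per-model temperature offsets — plus AR(1) daily
noise, independent across cells.  Values are written raw (unclamped), and
sentinel (10²⁰) and missing values are injected at configurable rates, so
the pipeline's QC is genuinely exercised.

Defaults (one choice, made at design time from the analytic truth table):

- 8 × 16 cells at 0.25°, centers −0.375°…1.375° N — straddles the equator
  so the hemisphere phase flip is active, biased north so boreal summer
  dominates;
- gradients far steeper than Earth's (−1.2 °C per degree |lat|,
  +3.2 °C per degree lon) so a 2° × 4° toy grid spans all five categories;
  tropical mean 35 °C, seasonal amplitude 5 °C, daily σ = 2 °C, AR(1) 0.6.
  This puts ≈ 25 % of toy land area in the Extreme band in baseline JJA,
  with every season expanding under warming — the qualitative regime of a
  real late-20th-century baseline;
- 3 models (one on a 360-day calendar), scenarios at 0.15 and 0.75
  °C/decade bracketing the transient response of a low- vs high-emission
  pathway, and 3-year mini-periods (1985–1987, 2040–2042, 2095–2097)
  standing in for the 30/25-year study windows.

The closed-form truth (`SyntheticTruth`) evaluates the noise-free signal
over the selected (year, day) pairs using plain month-length tables — no
NetCDF, no calendar library, no shared day-selection code — so the
end-to-end comparison crosses two independent implementations.  With zero
noise the pipeline must reproduce the truth's Extreme shares to < 10⁻⁹
before rounding; with noise, a delta-method envelope (per-variable
seasonal-mean noise sd inflated by (1+ρ)/(1−ρ) for AR(1) persistence,
propagated through the linearised BGT/HLI chain; a row's share may move by
at most the area of cells whose expected HLI lies within 5 sd of the
Extreme threshold) must cover the observed deviations in ≥ 99 % of
region × season rows.

What the generator does **not** emulate: realistic geography and spatial
covariance, cross-variable correlation (heat waves are jointly hot, dry and
sunny), humidity–temperature anticorrelation, leap days in the standard
calendar, and model spread beyond a mean temperature offset.  Passing the
synthetic suite therefore demonstrates the *correctness of the
computational chain* — QC, day selection across calendars, ensemble
weighting, formula evaluation, classification, area accounting — not the
realism of any projected number.  Results on real archive data inherit the
biases of that archive and of the empirical BGT/HLI calibrations.

## Numerical notes

- Missing data are NaN throughout; means are computed as finite-sum /
  finite-count, so all-missing cells stay missing without warnings.
- Classification uses a half-open-interval search (`searchsorted`,
  left side), making threshold membership exact in floating point.
- Cell areas are computed per latitude row and broadcast across longitude;
  summing a full-sphere 0.25° grid reproduces 4πR² to ~10⁻¹⁶ relative
  error.
- QC injection in the generator can flip a classification only for cells
  whose noise-free HLI sits within the injection-induced mean-shift bound
  of a threshold (≪ 1 HLI unit at the default 1–2 % rates); the test suite
  asserts exact invariance for a time-constant signal and the bounded
  version for the cyclic default.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng([seed, model, scenario, variable, year])`
  substreams; identical configuration gives byte-identical archives.

## Problem sizes

The test suite and the acceptance script run the full chain on the desk
default (8 × 16 grid, 3 models, 2 scenarios, 3 × 3-year periods; one
zero-noise archive plus five noisy seeds), chosen so a complete run takes
minutes on one CPU.  The pipeline itself is size-agnostic: the same code
path processes an arbitrary number of models, years and grid cells, reading
one (model, scenario, variable, period) file set at a time.

## Known limitations

- No bias correction or downscaling: inputs are assumed already
  bias-adjusted on a common grid, and inputs on different grids are
  rejected rather than interpolated.
- The empirical BGT estimate ignores wind-dependent globe cooling; the HLI
  branch discontinuity is inherited from the published formulation.
- Seasonal-mean HLI understates exposure relative to daily HLI exceedance
  statistics (no accumulated-heat-load or duration metric is computed).
- Country shares at 0.25° misstate very small or very coastal countries
  (cell-center assignment).
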