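# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the known limitations of `kpgrowth`.

## Data model

A **growth interval** is one plot-level record: sampling-interval start and
end dates, the number of shoots measured, and the mean elongation rate
(mm/day) over the interval. A **daily pattern** is a date-indexed series
(growth rate, temperature, Kp, or residuals) labelled by growing season;
growth patterns exist only inside seasons and no operation ever bridges
the winter gap. A **paired record** is one day's triple
(GR_d, T_{d−1}, Kp_{d−1}) after day-prior alignment — drivers lead growth
by one day to preserve causality.

Conventions that the data sources leave open, fixed here once:

* An interval's rate is assigned to the days (start, end] — growth accrues
  up to and including the sampling day. This conserves growth mass:
  the daily values over an interval sum to rate × interval length.
* Smoothing (3-day centered moving average, shrinking at season edges) is
  applied to the mire-area pattern after plot averaging, per season.
* Daily Kp is the mean of the eight 3-h slots of the UTC day; the
  published record is 3-hourly and does not fix a daily reduction, so the
  aggregator is configurable (`mean` default, `max` available). Days with
  fewer than eight slots are dropped with a logged warning.
* Plot averaging is the unweighted mean over the plots reporting that
  date; no imputation anywhere.
* Campaign bookkeeping pools yearly rows as: counts sum; the two per-year
  means (sample size, sampling interval) pool as the unweighted mean of
  the yearly means, rounded half-up to one decimal.

## Trend models

**Growth seasonality** is a second-order polynomial in day-of-season,
fitted per season by ordinary least squares (each season needs ≥ 4 days).
Per-season fitting is the natural choice because growth exists only within
seasons; residuals therefore have zero mean within every season.

**Temperature seasonality** is a single annual sinusoid
c + a·sin(2π(t + φ)/P) fitted by linear least squares on the basis
{1, sin, cos} with t in days since the series start. The default period is
P = 365.3 d; `scan_period` fits a candidate grid and selects the best
period by R² (ties to the smaller period). A warning is issued when the
series spans less than one period. Detrending is idempotent: refitting the
residuals returns amplitude ≈ 0.

## The gradient analysis

Records sorted ascending by Kp (stable, ties broken by date) are windowed
with a fixed window of n_w = 200 records, step 1. Each window's Pearson r
is computed directly on the slice via a strided view — no cumulative-sum
shortcut — so every window agrees with an independent Pearson computation
to ~1e−15. Window location is summarised by the arithmetic mean Kp
(median also computed; selectable for interval detection).

P-values use t = r√((n−2)/(1−r²)) on n−2 df, two-sided, in log₁₀ space.
Within float range this is scipy's survival function; deeper in the tail
it switches to the incomplete-beta representation
sf = I_x(ν/2, ½)/2, x = ν/(ν+t²), evaluated by a direct hypergeometric
series, giving finite exponents for |t| in the hundreds.

**Favorable-interval detection** (the field literature states no rule, so
this is the package's own construction, configurable): flag windows with
r ≥ a reference level (default: the global r of the same records), form
maximal contiguous runs of flagged windows, and report the run containing
the maximum-r window as [min, max] of its window Kp statistic. The share
of monitoring days whose day-prior Kp falls inside the interval is
reported as a percentage to one decimal.

Boundary estimates from this rule carry substantial sampling noise at the
campaign scale (~1440 records): the reference sits less than one profile
standard deviation above the off-window baseline, so flagged runs
occasionally extend through off-window stretches whose r drifts above the
reference, displacing one boundary by up to ~0.4 Kp. Recovery simulations
(20 seeded campaigns) locate the injected window's boundaries within
0.25 Kp on both ends in ~75% of replicates; alternative location
statistics (window median Kp, half-prominence trimming of the run) do not
improve this. Treat detected boundaries as estimates with ~±0.2 Kp
uncertainty at this problem size.

**Permutation null.** The Kp column is permuted against the fixed
(growth, temperature) pairs (≥100 permutations; 500 used in the checks),
the profile recomputed each time, and pointwise 2.5/50/97.5% quantiles
reported per window index. Note the null's limitation: permutation builds
windows from exchangeable record subsets, while the observed windows
contain temporally clustered records (Kp and weather are autocorrelated),
so the observed profile genuinely has somewhat larger variance than the
envelope even without any injected modulation — long excursions should be
interpreted against this backdrop, with the envelope read as a lower bound
on null variability. In calibration runs without injected modulation the
observed profile stays inside the 95% envelope at a median of ~98% of
windows, but individual campaigns can dip to ~76–86%.

## Diurnal profiling

For each canonical hour h ∈ {0,3,…,21} the growth pattern is aligned with
that hour's temperature of the previous day and the identical sort/window
machinery is run, producing an 8 × windows matrix plus a full-data
per-hour r profile. All hours must align to the same record set so
columns are comparable. The bimodality score is
½(max r over {6,9} + max r over {18,21}) − min r over {12,15}: positive
for a morning/evening-peaked, midday-dipped profile, zero for a flat one.
Air and soil-surface temperature are handled as two input files through
the identical path. On raw patterns the hours share the entire seasonal
signal, so hour differences are second-order; the informative profile is
computed on detrended growth against per-hour detrended temperature, the
route used in the recovery checks.

## Synthetic campaigns

The generator's defaults emulate the monitoring design: 8 seasons
(day-of-year 110–290, i.e. late April to mid October, starting 2015),
2-day sampling intervals tiling each season (last interval truncated),
6 plots, 40 shoots per sample, one preceding driver day so day-prior
alignment never truncates. This yields ~1440 mire-area daily growth
values, matching the field campaign's scale.

* **Temperature.** Daily mean = 4 °C + 12 °C · sin(2π(t−t₀)/365.3) (peak
  at mid-July) + stationary AR(1) noise (lag-1 ρ = 0.7, marginal sd 3 °C).
  Hourly values add a fixed diurnal cycle (amplitude 4 °C, peak 15 h) and
  per-hour noise (sd 3 °C) centered within each day, so the eight hours
  average exactly to the daily mean.
* **Kp.** A stationary Gaussian AR(1) (lag-1 ρ = 0.8 on the 3-h grid)
  mapped through kp = 1.2·exp(z) (median 1.2, log-scale sd 1 — a
  right-skewed marginal with most daily means below 3), clipped to [0, 9]
  and snapped to the published thirds grid (ties up). A log-scale sd of 0
  degenerates to a constant series.
* **Growth.** True rate(d) = max(0, hump(d) + β(Kp_{d−1})·a(d−1) + ε_d)
  with a quadratic hump (0 at season edges, 4 mm/day mid-season), daily
  process noise ε (sd 0.3 mm/day), and anomaly a = temperature departure
  from the annual sinusoid. β(Kp) = β₀(1+κ) for Kp inside the injected
  window (defaults β₀ = 0.15 mm/day/°C, κ = 1, window [0.9, 1.6]), β₀
  outside; κ = 0 gives a Kp-independent coupling. With non-uniform hour
  weights the anomaly additionally mixes the centered per-hour departures
  (weighted, normalised) so chosen hours carry the coupling; with uniform
  weights this channel cancels exactly. Plot records average 40 noisy
  per-shoot rates (sd 1.5 mm/day), so plot and mire averaging genuinely
  reduce variance.

All three generators draw from independent substreams of a single seed;
identical configurations reproduce bit-identical outputs.

What the generator does **not** emulate: solar–terrestrial physics of Kp,
water-table or moisture dynamics, measurement-method artifacts, gaps, or
the much larger unexplained growth variance of real campaigns — synthetic
raw correlations (~0.9) are far cleaner than field values (~0.6). Passing
recovery tests therefore demonstrates the machinery's correctness and its
behaviour under known coupling, not field-scale effect sizes.

## Problem sizes used in the checks

The test suite and the acceptance script run full default campaigns
(~1440 records, window 200), 20-seed replicate sweeps for recovery,
attenuation and calibration, 500-permutation envelopes, and 100 randomized
inputs for the window oracle; the acceptance script uses 10 replicates for
its rate summaries.

## Known limitations

* The daily-Kp reduction (mean of slots) is a convention, not a sourced
  choice; conclusions sensitive to it should be checked with `max`.
* Interval detection boundaries have ~±0.2 Kp sampling noise at this
  campaign size (see above); the detection rule itself is a construction,
  not a published procedure.
* The permutation envelope understates null variability for autocorrelated
  drivers (see above).
* The harmonic model is a single sinusoid plus offset; no multi-harmonic
  decomposition or spline alternatives.
* No gap imputation and no reconstruction of shoot-level measurements.
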