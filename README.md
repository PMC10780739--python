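# kpgrowth

Does geomagnetic activity modulate how plants respond to temperature?
Long-term field monitoring of the peat moss *Sphagnum riparium* suggests it
does: the correlation between daily shoot growth rate and temperature is not
constant but changes along the gradient of the planetary geomagnetic **Kp
index**, with a "favorable" band of quiet-to-moderate activity (roughly
Kp 0.87–1.61 in the field campaign) where the temperature growth response is
strongest.

`kpgrowth` is a tested, reusable implementation of that analysis for
interval-sampled growth monitoring data, together with a synthetic campaign
generator with known ground truth, so every stage can be validated by
parameter recovery rather than by eye.

## The analysis

Inputs are (a) plot-level sampling intervals with mean elongation rates
(mm/day), (b) daily and 3-hourly temperature (°C), and (c) the 3-hourly Kp
series (0–9 in thirds).

1. **Pattern construction.** Each interval's rate is extrapolated to its
   covered days, plots are averaged into a mire-area daily pattern
   GR(d), and the pattern is smoothed with a centered 3-day moving average
   (within seasons only).
2. **Day-prior pairing.** Each growth day d is paired with the previous
   day's drivers: records (GR_d, T_{d−1}, Kp_{d−1}), where daily Kp is the
   mean of the eight 3-h slots.
3. **Global response.** Pearson r between GR and T, with the two-sided
   p-value from t = r·√((n−2)/(1−r²)) on n−2 df kept in log₁₀ space (so
   exponents like −119 or −575 never underflow).
4. **Kp-gradient profile.** Records are sorted by Kp and r(GR, T) is
   computed in a sliding window of 200 records (step 1); each window is
   summarised by its mean Kp, giving a profile r(Kp). A maximal contiguous
   run of windows with r ≥ the global r, containing the maximum-r window,
   is reported as the favorable Kp interval, along with the share of
   monitoring days falling inside it. A permutation null (Kp shuffled
   against fixed pairs) gives a pointwise 95% envelope for the profile.
5. **Detrending.** The seasonal hump is removed from growth (ordinary
   least-squares quadratic per season) and the annual cycle from
   temperature (single sinusoid, period 365.3 d selected by R² over a
   period grid); the gradient analysis is repeated on the residuals —
   the response to short-term temperature fluctuations.
6. **Diurnal profiling.** Steps 2–4 are repeated against the temperature
   at each of the eight observation hours {00,03,…,21}, yielding an
   hours × windows matrix of r and a per-hour profile whose bimodal shape
   (morning 06–09 h and evening 18–21 h peaks, midday 12–15 h trough) is
   scored as mean(peaks) − trough.

The synthetic generator emulates the campaign (≥8 April–October seasons,
~2-day intervals on several plots, AR(1) weather noise on an annual
sinusoid, right-skewed autocorrelated Kp on the thirds grid) and injects a
known coupling: growth responds to the day-prior temperature anomaly with
slope β(Kp) = β₀(1+κ) inside a configurable Kp window and β₀ outside,
optionally routed through specific hours of the day.

## Worked example

Run the whole pipeline on a default synthetic campaign (8 seasons, ~1440
paired records, injected favorable window Kp ∈ [0.9, 1.6] with κ = 1):

```sh
kpgrowth all --seed 7 --out-dir kpdemo
```

which writes the input CSVs, window profiles, interval JSON, diurnal
matrix and a one-page summary:

```
kpgrowth 0.1.0 summary  (seed 7, 1440 paired records)
========================================================================
Raw patterns:
  growth vs temperature   r = +0.908  (n = 1440, log10 p = -545.0)
  growth vs Kp (direct)   r = +0.019  (n = 1440, log10 p = -0.3)
  Kp < 0.87:              r = +0.899  (n = 341, log10 p = -122.6)
  Kp in [0.87, 1.61]:     r = +0.927  (n = 448, log10 p = -191.2)
  Kp > 1.61:              r = +0.901  (n = 651, log10 p = -236.5)
  favorable Kp interval:  [0.86, 1.50]  (r inside = +0.927, n = 412)
  days inside interval:   28.6%
  days inside [0.87, 1.61]: 31.1%
Detrended residuals:
  growth vs temperature   r = +0.812  (n = 1440, log10 p = -337.4)
  ...
```

Reading it: growth tracks temperature strongly overall; there is *no*
direct growth–Kp correlation (r ≈ 0.02) even though Kp modulates the
coupling; the detected favorable interval [0.86, 1.50] recovers the
injected [0.9, 1.6] to within the window-resolution limit; about 30% of
monitoring days fall inside it; and detrending lowers the global r, as the
shared seasonal cycle is removed.

The same stages are available piecewise (`kpgrowth simulate / prepare /
detrend / gradient / diurnal / summary`), all driven by a YAML config and
a single seed; reruns are byte-identical.

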