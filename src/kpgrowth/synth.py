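"""Synthetic monitoring campaigns with known ground-truth coupling.

The published growth-rate series is not deposited, so every downstream
stage is exercised on simulated campaigns that emulate the field design:
an April--October growing season repeated over several years, plot-level
growth sampled at ~2-day intervals, daily temperature with an annual
sinusoid plus AR(1) weather noise and a fixed diurnal cycle, and a
right-skewed autocorrelated Kp series on the 3-hourly thirds grid.

Growth couples to the previous day's temperature anomaly with slope
``beta0``, boosted by a factor ``(1 + kappa)`` whenever the previous
day's Kp falls inside a configurable "favorable" window -- the effect the
gradient analysis is meant to recover.  Optional per-hour weights route
the coupling through specific observation hours of the diurnal table,
giving the diurnal analysis a recoverable bimodal target; with the
default uniform weights the hour-specific channel cancels exactly and the
coupling is purely daily.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .patterns import DailyPattern
from .prepare import CANONICAL_HOURS

#: Day of year of the warmest day of the annual temperature sinusoid.
TEMP_PEAK_DOY = 196

# independent, reproducible substreams per generator stage
_STREAM_KP, _STREAM_TEMP, _STREAM_GROWTH = 1, 2, 3


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate the monitored field campaign."""

    seed: int = 0
    n_seasons: int = 8
    season_doy: tuple = (110, 290)  # second half of April .. second half of October
    sampling_interval_days: int = 2
    n_plots: int = 6
    shoots_per_sample: int = 40
    temp_mean: float = 4.0  # degC, boreal annual mean
    temp_annual_amplitude: float = 12.0  # degC
    temp_period_days: float = 365.3
    temp_ar_rho: float = 0.7
    temp_noise_sd: float = 3.0  # degC, marginal sd of the AR(1) weather noise
    diurnal_amplitude: float = 4.0  # degC
    hourly_noise_sd: float = 3.0  # degC, per-hour scatter about mean + diurnal cycle
    kp_ar_rho: float = 0.8
    kp_skew: float = 1.0  # log-scale sd of the right-skewed Kp marginal
    kp_median: float = 1.2  # Kp units, marginal median of the latent process
    beta0: float = 0.15  # mm/day per degC
    kp_window: tuple = (0.9, 1.6)  # favorable Kp range [k_lo, k_hi]
    kappa: float = 1.0  # fractional slope boost inside kp_window
    hour_weights: tuple = (1.0,) * 8  # coupling weight per canonical hour
    season_peak_rate: float = 4.0  # mm/day at mid-season
    daily_noise_sd: float = 0.3  # mm/day, daily process noise
    shoot_noise_sd: float = 1.5  # mm/day, per-shoot measurement noise
    start_year: int = 2015

    def validate(self) -> None:
        lo, hi = self.kp_window
        if not lo < hi:
            raise ValueError(f"kp_window must satisfy k_lo < k_hi, got {self.kp_window}")
        d0, d1 = self.season_doy
        if not (1 <= d0 < d1 <= 366):
            raise ValueError(f"season_doy must lie in [1, 366] with start < end, got {self.season_doy}")
        for name in ("temp_noise_sd", "hourly_noise_sd", "daily_noise_sd", "shoot_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.temp_annual_amplitude < 0 or self.diurnal_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        for name in ("temp_ar_rho", "kp_ar_rho"):
            rho = getattr(self, name)
            if not 0.0 <= rho < 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {rho}")
        if self.kappa < -1:
            raise ValueError("kappa must be >= -1")
        if self.n_seasons < 1 or self.n_plots < 1 or self.shoots_per_sample < 1:
            raise ValueError("counts must be >= 1")
        if self.sampling_interval_days < 1:
            raise ValueError("sampling_interval_days must be >= 1")
        w = np.asarray(self.hour_weights, dtype=float)
        if w.shape != (8,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("hour_weights must be 8 nonnegative values with positive sum")

    # -- campaign calendar -------------------------------------------
    def season_dates(self, year: int) -> pd.DatetimeIndex:
        d0, d1 = self.season_doy
        base = pd.Timestamp(year, 1, 1)
        return pd.date_range(
            base + pd.Timedelta(days=d0 - 1), base + pd.Timedelta(days=d1 - 1), freq="D"
        )

    @property
    def years(self) -> range:
        return range(self.start_year, self.start_year + self.n_seasons)

    def driver_dates(self) -> pd.DatetimeIndex:
        """Continuous daily span: one day before the first season day
        through the last season day (day-prior alignment never truncates)."""
        first = self.season_dates(self.years[0])[0] - pd.Timedelta(days=1)
        last = self.season_dates(self.years[-1])[-1]
        return pd.date_range(first, last, freq="D")


@dataclass
class SimulatedTruth:
    """Ground truth injected by the generator, for recovery tests."""

    daily: pd.DataFrame  # date, true_rate, beta, kp_prev, anomaly_prev
    kp_window: tuple
    hour_weights: tuple


@dataclass
class Campaign:
    config: SyntheticConfig
    kp_3h: pd.Series
    temp_daily: DailyPattern
    temp_hourly: pd.DataFrame
    intervals: pd.DataFrame
    truth: SimulatedTruth


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _ar1(rng: np.random.Generator, n: int, rho: float, marginal_sd: float) -> np.ndarray:
    """Stationary AR(1) with the given lag-1 rho and marginal sd."""
    eps = rng.standard_normal(n)
    if marginal_sd == 0 or n == 0:
        return np.zeros(n)
    innov = eps * np.sqrt(1.0 - rho * rho)
    innov[0] = eps[0]  # stationary start
    z = lfilter([1.0], [1.0, -rho], innov)
    return marginal_sd * z


def snap_to_thirds(kp: np.ndarray) -> np.ndarray:
    """Snap to the published Kp thirds grid, ties rounding up."""
    return np.floor(np.asarray(kp, dtype=float) * 3.0 + 0.5) / 3.0


def harmonic_mean_temperature(config: SyntheticConfig, dates: pd.DatetimeIndex) -> np.ndarray:
    """The deterministic annual sinusoid of daily mean temperature."""
    t = (dates - pd.Timestamp(config.start_year, 1, 1)).days.to_numpy(dtype=float)
    p = config.temp_period_days
    t0 = (TEMP_PEAK_DOY - 1) - p / 4.0  # sin peaks at the warmest day
    return config.temp_mean + config.temp_annual_amplitude * np.sin(2.0 * np.pi * (t - t0) / p)


def diurnal_offsets(config: SyntheticConfig) -> np.ndarray:
    """Deterministic diurnal cycle at the canonical hours (peak at 15 h);
    the eight equally spaced phases sum to zero, so the daily mean is untouched."""
    h = np.asarray(CANONICAL_HOURS, dtype=float)
    return config.diurnal_amplitude * np.sin(2.0 * np.pi * (h - 9.0) / 24.0)


def seasonal_hump(config: SyntheticConfig, dates: pd.DatetimeIndex) -> np.ndarray:
    """Quadratic seasonal growth course: 0 at the season edges, peak mid-season."""
    d0, d1 = config.season_doy
    doy = dates.dayofyear.to_numpy(dtype=float)
    x = (doy - d0) / (d1 - d0)
    return config.season_peak_rate * 4.0 * x * (1.0 - x)


# ----------------------------------------------------------------------
# Drivers
# ----------------------------------------------------------------------

def simulate_kp(config: SyntheticConfig) -> pd.Series:
    """3-hourly Kp over the driver span.

    A stationary Gaussian AR(1) latent process is mapped through a
    monotone lognormal-type transform ``kp_median * exp(kp_skew * z)`` to
    a right-skewed marginal, clipped to [0, 9], and snapped to the thirds
    grid.  ``kp_skew -> 0`` collapses to a constant (degenerate) series.
    """
    config.validate()
    days = config.driver_dates()
    if len(days) == 0:
        raise ValueError("driver span is empty")
    idx = pd.DatetimeIndex(
        [d + pd.Timedelta(hours=h) for d in days for h in CANONICAL_HOURS]
    )
    rng = _rng(config, _STREAM_KP)
    z = _ar1(rng, len(idx), config.kp_ar_rho, 1.0)
    kp = config.kp_median * np.exp(config.kp_skew * z)
    kp = snap_to_thirds(np.clip(kp, 0.0, 9.0))
    return pd.Series(kp, index=idx, name="kp")


def simulate_temperature(config: SyntheticConfig) -> tuple[DailyPattern, pd.DataFrame]:
    """Daily-mean temperature and the eight-hour diurnal table.

    Daily mean = annual sinusoid + stationary AR(1) weather noise.  The
    hourly value adds the fixed diurnal cycle plus per-hour noise that is
    centered within each day, so the mean over the eight hours reproduces
    the daily mean exactly.
    """
    config.validate()
    days = config.driver_dates()
    rng = _rng(config, _STREAM_TEMP)
    mean = harmonic_mean_temperature(config, days)
    noise = _ar1(rng, len(days), config.temp_ar_rho, config.temp_noise_sd)
    daily_values = mean + noise
    daily = DailyPattern(pd.Series(daily_values, index=days), "degC")

    offsets = diurnal_offsets(config)
    eta = rng.standard_normal((len(days), 8)) * config.hourly_noise_sd
    eta -= eta.mean(axis=1, keepdims=True)  # center within each day
    temps = daily_values[:, None] + offsets[None, :] + eta
    hourly = pd.DataFrame(
        {
            "date": np.repeat(days, 8),
            "hour": np.tile(np.asarray(CANONICAL_HOURS), len(days)),
            "temp_c": temps.ravel(),
        }
    )
    return daily, hourly


# ----------------------------------------------------------------------
# Growth
# ----------------------------------------------------------------------

def beta_of_kp(config: SyntheticConfig, kp: np.ndarray) -> np.ndarray:
    """Coupling slope as a function of (day-prior) Kp: ``beta0 * (1 + kappa)``
    inside the closed favorable window, ``beta0`` outside."""
    lo, hi = config.kp_window
    inside = (np.asarray(kp, dtype=float) >= lo) & (np.asarray(kp, dtype=float) <= hi)
    return config.beta0 * (1.0 + config.kappa * inside)


def simulate_growth(
    kp_daily: DailyPattern,
    temp_daily: DailyPattern,
    config: SyntheticConfig,
    temp_hourly: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, SimulatedTruth]:
    """Per-plot growth-interval records plus the injected ground truth.

    The true rate on season day d is
    ``max(0, hump(d) + beta(Kp_{d-1}) * anomaly(d-1) + process noise)``
    where the anomaly is the temperature departure from the annual
    sinusoid -- the day-prior convention of the analysis.  With a diurnal
    table and non-uniform ``hour_weights`` the anomaly additionally mixes
    each hour's centered departure, weighted and normalised, so specified
    hours carry the coupling.  Plot records are means of
    ``shoots_per_sample`` noisy per-shoot rates over each sampling
    interval; intervals tile each season, the last truncated at season
    end.
    """
    config.validate()
    rng = _rng(config, _STREAM_GROWTH)

    season_days = [config.season_dates(y) for y in config.years]
    all_days = season_days[0].append(season_days[1:]) if len(season_days) > 1 else season_days[0]
    needed = pd.DatetimeIndex(sorted(set(all_days) | {d - pd.Timedelta(days=1) for d in all_days}))
    for name, pat in (("kp", kp_daily), ("temperature", temp_daily)):
        missing = needed.difference(pat.dates)
        if len(missing):
            raise ValueError(f"{name} driver missing for {missing[0].date()}")

    # day-prior drivers
    prev = all_days - pd.Timedelta(days=1)
    kp_prev = kp_daily.data.reindex(prev).to_numpy(dtype=float)
    anomaly = (temp_daily.data.reindex(prev).to_numpy(dtype=float)
               - harmonic_mean_temperature(config, prev))
    w = np.asarray(config.hour_weights, dtype=float)
    w_norm = w / w.sum()
    if temp_hourly is not None and not np.allclose(w_norm, 1.0 / 8.0):
        # hour-specific channel: weighted centered hourly departures of day d-1
        piv = temp_hourly.pivot(index="date", columns="hour", values="temp_c")
        piv = piv.reindex(columns=list(CANONICAL_HOURS))
        missing = prev.difference(piv.index)
        if len(missing):
            raise ValueError(f"hourly temperature missing for {missing[0].date()}")
        hourly_dep = piv.reindex(prev).to_numpy(dtype=float)
        hourly_dep = hourly_dep - hourly_dep.mean(axis=1, keepdims=True) - diurnal_offsets(config)
        anomaly = anomaly + hourly_dep @ w_norm

    beta = beta_of_kp(config, kp_prev)
    hump = seasonal_hump(config, all_days)
    eps = rng.standard_normal(len(all_days)) * config.daily_noise_sd
    true_rate = np.maximum(0.0, hump + beta * anomaly + eps)
    true = pd.Series(true_rate, index=all_days)

    records = []
    for year, days in zip(config.years, season_days):
        bounds = list(days[:: config.sampling_interval_days])
        if bounds[-1] != days[-1]:
            bounds.append(days[-1])  # truncated final interval
        for a, b in zip(bounds[:-1], bounds[1:]):
            covered = pd.date_range(a + pd.Timedelta(days=1), b, freq="D")
            true_mean = float(true.loc[covered].mean())
            for plot in range(1, config.n_plots + 1):
                shoots = true_mean + rng.standard_normal(config.shoots_per_sample) * config.shoot_noise_sd
                records.append(
                    {
                        "plot_id": f"P{plot:02d}",
                        "start_date": a,
                        "end_date": b,
                        "n_shoots": config.shoots_per_sample,
                        "rate_mm_day": max(0.0, float(shoots.mean())),
                    }
                )
    intervals = pd.DataFrame.from_records(records)
    truth = SimulatedTruth(
        daily=pd.DataFrame(
            {
                "date": all_days,
                "true_rate": true_rate,
                "beta": beta,
                "kp_prev": kp_prev,
                "anomaly_prev": anomaly,
            }
        ),
        kp_window=tuple(config.kp_window),
        hour_weights=tuple(config.hour_weights),
    )
    return intervals, truth


# ----------------------------------------------------------------------
# Whole campaigns and file output
# ----------------------------------------------------------------------

def simulate_campaign(config: SyntheticConfig) -> Campaign:
    """Run all three generators consistently from one seed."""
    from .prepare import daily_kp  # local import to avoid cycles at module load

    kp_3h = simulate_kp(config)
    temp_daily, temp_hourly = simulate_temperature(config)
    kp_day = daily_kp(kp_3h, "mean")
    intervals, truth = simulate_growth(kp_day, temp_daily, config, temp_hourly=temp_hourly)
    return Campaign(
        config=config,
        kp_3h=kp_3h,
        temp_daily=temp_daily,
        temp_hourly=temp_hourly,
        intervals=intervals,
        truth=truth,
    )


def write_campaign(campaign: Campaign, out_dir) -> dict:
    """Write the standard input CSVs plus the ground-truth table.

    Emits ``growth.csv`` (plot_id,start_date,end_date,n_shoots,rate_mm_day),
    ``temperature.csv`` (date,hour,temp_c; daily-mean rows have empty hour),
    ``kp.csv`` (datetime_utc,kp) and ``truth.csv``.  Returns path manifest.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    growth = campaign.intervals.copy()
    growth["start_date"] = growth["start_date"].dt.strftime("%Y-%m-%d")
    growth["end_date"] = growth["end_date"].dt.strftime("%Y-%m-%d")
    paths["growth"] = out / "growth.csv"
    growth.to_csv(paths["growth"], index=False)

    daily = pd.DataFrame(
        {
            "date": campaign.temp_daily.dates.strftime("%Y-%m-%d"),
            "hour": "",
            "temp_c": campaign.temp_daily.values,
        }
    )
    hourly = campaign.temp_hourly.copy()
    hourly["date"] = hourly["date"].dt.strftime("%Y-%m-%d")
    paths["temperature"] = out / "temperature.csv"
    pd.concat([daily, hourly]).to_csv(paths["temperature"], index=False)

    kp = pd.DataFrame(
        {
            "datetime_utc": campaign.kp_3h.index.strftime("%Y-%m-%dT%H:%M:%S"),
            "kp": campaign.kp_3h.to_numpy(),
        }
    )
    paths["kp"] = out / "kp.csv"
    kp.to_csv(paths["kp"], index=False)

    truth = campaign.truth.daily.copy()
    truth["date"] = truth["date"].dt.strftime("%Y-%m-%d")
    paths["truth"] = out / "truth.csv"
    truth.to_csv(paths["truth"], index=False)
    return {k: str(v) for k, v in paths.items()}


def config_with(config: SyntheticConfig, **overrides) -> SyntheticConfig:
    """A copy of ``config`` with fields replaced (convenience for sweeps)."""
    return replace(config, **overrides)
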