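"""Diurnal temperature response: the gradient analysis per time of day.

Instead of the daily-mean temperature, the growth pattern is paired with
the temperature at each of the eight 3-hourly observation times of the
previous day.  Running the identical sort-by-Kp sliding-window analysis
per hour yields an hours-by-windows matrix of correlation coefficients,
and the full-data per-hour r profile.  Field observations show that the
profile is bimodal -- stronger response to morning (06-09 h) and evening
(18-21 h) temperature than to midday (12-15 h); the bimodality score
quantifies that shape as ``mean(morning peak, evening peak) - midday
trough``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gradient, trend
from .patterns import DailyPattern
from .prepare import CANONICAL_HOURS, lag_align

MORNING_HOURS = (6, 9)
MIDDAY_HOURS = (12, 15)
EVENING_HOURS = (18, 21)


@dataclass
class DiurnalResponseMatrix:
    """Windowed r per hour (rows) and window (columns), plus full-data r."""

    hours: tuple
    window_r: pd.DataFrame  # index = hour, columns = window index
    kp_mean: np.ndarray  # per window, from the Kp-sorted records
    full_r: pd.Series  # per-hour Pearson r on all aligned pairs
    full_n: pd.Series  # per-hour pair count
    window: int


@dataclass
class BimodalityScore:
    morning_peak: float
    evening_peak: float
    midday_trough: float

    @property
    def score(self) -> float:
        return 0.5 * (self.morning_peak + self.evening_peak) - self.midday_trough


def hourly_pattern(hourly: pd.DataFrame, hour: int) -> DailyPattern:
    """Extract one observation hour of the diurnal table as a daily pattern."""
    sub = hourly[hourly["hour"] == hour]
    if sub.empty:
        raise ValueError(f"hour {hour:02d} missing from the diurnal temperature table")
    return DailyPattern(
        pd.Series(sub["temp_c"].to_numpy(dtype=float), index=pd.DatetimeIndex(sub["date"])),
        "degC",
    )


def detrend_hourly_temperature(
    hourly: pd.DataFrame, period: float = 365.3
) -> pd.DataFrame:
    """Remove the annual harmonic from each hour's series independently.

    Returns a diurnal table of residuals with the same (date, hour) rows,
    for profiling the response to short-term temperature fluctuations.
    """
    parts = []
    for hour in CANONICAL_HOURS:
        pat = hourly_pattern(hourly, hour)
        _, resid = trend.fit_harmonic(pat, period)
        parts.append(
            pd.DataFrame({"date": resid.dates, "hour": hour, "temp_c": resid.values})
        )
    return pd.concat(parts).sort_values(["date", "hour"]).reset_index(drop=True)


def diurnal_response_matrix(
    growth: DailyPattern,
    hourly: pd.DataFrame,
    kp: DailyPattern,
    window: int = 200,
    lag: int = 1,
) -> DiurnalResponseMatrix:
    """Sliding-window growth-temperature r along the Kp gradient, per hour.

    For each canonical hour the growth pattern is day-prior aligned with
    that hour's temperature and the daily Kp, sorted by Kp, and windowed
    exactly as in :mod:`kpgrowth.gradient`.  All hours must align to the
    same record set so the matrix columns are comparable.
    """
    missing = [h for h in CANONICAL_HOURS if h not in set(hourly["hour"])]
    if missing:
        raise ValueError(
            f"diurnal table lacks canonical hour(s): {', '.join(f'{h:02d}' for h in missing)}"
        )
    rows, full_r, full_n = {}, {}, {}
    kp_mean = None
    n_ref = None
    for hour in CANONICAL_HOURS:
        temp_h = hourly_pattern(hourly, hour)
        records = lag_align(growth, temp_h, kp, lag=lag)
        if n_ref is None:
            n_ref = len(records)
        elif len(records) != n_ref:
            raise ValueError(
                f"hour {hour:02d} aligns to {len(records)} records but hour "
                f"{CANONICAL_HOURS[0]:02d} to {n_ref}; supply a complete diurnal table"
            )
        ordered = gradient.sort_by_kp(records)
        stats = gradient.sliding_window_correlation(ordered, window=window)
        rows[hour] = stats["r"].to_numpy()
        if kp_mean is None:
            kp_mean = stats["kp_mean"].to_numpy()
        corr = gradient.pearson(records["growth_rate"], records["temperature"])
        full_r[hour] = corr.r
        full_n[hour] = corr.n
    window_r = pd.DataFrame.from_dict(rows, orient="index")
    window_r.index.name = "hour"
    return DiurnalResponseMatrix(
        hours=CANONICAL_HOURS,
        window_r=window_r,
        kp_mean=kp_mean,
        full_r=pd.Series(full_r, name="r"),
        full_n=pd.Series(full_n, name="n"),
        window=window,
    )


def bimodality_score(profile) -> BimodalityScore:
    """Score the bimodal shape of a per-hour r profile.

    ``profile`` maps hour -> r (e.g. ``DiurnalResponseMatrix.full_r``, or
    one Kp-subrange column).  Positive scores mean morning/evening peaks
    with a midday trough; a flat profile scores exactly zero.
    """
    if isinstance(profile, DiurnalResponseMatrix):
        profile = profile.full_r
    prof = pd.Series(profile)
    for h in MORNING_HOURS + MIDDAY_HOURS + EVENING_HOURS:
        if h not in prof.index:
            raise ValueError(f"profile lacks hour {h:02d}")
    return BimodalityScore(
        morning_peak=float(prof[list(MORNING_HOURS)].max()),
        evening_peak=float(prof[list(EVENING_HOURS)].max()),
        midday_trough=float(prof[list(MIDDAY_HOURS)].min()),
    )
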