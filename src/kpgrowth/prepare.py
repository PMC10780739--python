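"""From raw interval measurements to analysis-ready paired daily records.

Growth is sampled on plots at ~2-day intervals; each interval yields one
mean elongation rate (mm/day).  This module extrapolates interval rates to
their covered days, averages plots into a mire-area pattern, smooths it
with a short centered moving average, reduces 3-hourly Kp to daily values,
and pairs each growth day with the previous day's temperature and Kp
(day-prior alignment, preserving causality).  It also reproduces the
campaign bookkeeping summary (per-year and pooled monitoring parameters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .patterns import DailyPattern

logger = logging.getLogger(__name__)

GROWTH_COLUMNS = ["plot_id", "start_date", "end_date", "n_shoots", "rate_mm_day"]

#: The canonical 3-hourly observation hours (UTC interval start hours).
CANONICAL_HOURS = (0, 3, 6, 9, 12, 15, 18, 21)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ----------------------------------------------------------------------
# CSV readers / writers
# ----------------------------------------------------------------------

def read_growth_csv(path) -> pd.DataFrame:
    """Read the growth-interval table (plot_id,start_date,end_date,n_shoots,rate_mm_day)."""
    df = pd.read_csv(path)
    missing = set(GROWTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"growth CSV {path} lacks columns: {sorted(missing)}")
    df["start_date"] = pd.to_datetime(df["start_date"])
    df["end_date"] = pd.to_datetime(df["end_date"])
    return df


def read_temperature_csv(path) -> tuple[DailyPattern, pd.DataFrame]:
    """Read temperature CSV (date,hour,temp_c).

    Rows with an empty ``hour`` field are daily means; rows with hour in
    {0,3,...,21} form the diurnal table.  If no daily rows are present the
    daily series is the mean over the eight hours of each complete day.
    """
    df = pd.read_csv(path)
    for col in ("date", "hour", "temp_c"):
        if col not in df.columns:
            raise ValueError(f"temperature CSV {path} lacks column {col!r}")
    df["date"] = pd.to_datetime(df["date"])
    daily_rows = df[df["hour"].isna()]
    hourly = df[df["hour"].notna()].copy()
    if not hourly.empty:
        hourly["hour"] = hourly["hour"].astype(int)
        bad = set(hourly["hour"]) - set(CANONICAL_HOURS)
        if bad:
            raise ValueError(f"non-canonical hours in temperature CSV: {sorted(bad)}")
        hourly = hourly.sort_values(["date", "hour"]).reset_index(drop=True)
    if not daily_rows.empty:
        s = daily_rows.set_index("date")["temp_c"].sort_index()
    else:
        counts = hourly.groupby("date")["temp_c"].count()
        full = counts[counts == len(CANONICAL_HOURS)].index
        s = hourly[hourly["date"].isin(full)].groupby("date")["temp_c"].mean()
    return DailyPattern(s, "degC"), hourly[["date", "hour", "temp_c"]]


def read_kp_csv(path) -> pd.Series:
    """Read the 3-hourly Kp CSV (datetime_utc,kp) into a datetime-indexed series."""
    df = pd.read_csv(path)
    for col in ("datetime_utc", "kp"):
        if col not in df.columns:
            raise ValueError(f"kp CSV {path} lacks column {col!r}")
    s = pd.Series(
        df["kp"].to_numpy(dtype=float), index=pd.DatetimeIndex(pd.to_datetime(df["datetime_utc"]))
    ).sort_index()
    if ((s < 0) | (s > 9)).any():
        raise ValueError("Kp values outside [0, 9]")
    return s


def parse_gfz_kp(path) -> pd.Series:
    """Parse the GFZ ``Kp_ap`` whitespace text format into a 3-hourly series.

    Expects data lines starting ``YYYY MM DD ...`` with the eight Kp values
    in columns 8-15 (as in the public ``Kp_ap_since_1932`` files); ``#``
    lines are skipped.
    """
    dates, hours, values = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 15:
                raise ValueError(f"unparseable Kp line: {line[:60]!r}")
            y, m, d = int(parts[0]), int(parts[1]), int(parts[2])
            for i, h in enumerate(CANONICAL_HOURS):
                dates.append(pd.Timestamp(y, m, d) + pd.Timedelta(hours=h))
                values.append(float(parts[7 + i]))
    return pd.Series(values, index=pd.DatetimeIndex(dates)).sort_index()


# ----------------------------------------------------------------------
# Pattern construction
# ----------------------------------------------------------------------

def intervals_to_daily(intervals: pd.DataFrame, units: str = "mm/day") -> DailyPattern:
    """Extrapolate one plot's interval rates to every covered day.

    Each sampling interval's mean rate is carried to the days
    ``(start_date, end_date]`` -- growth accrues up to and including the
    sampling day.  Days covered by no interval are absent.  Overlapping
    intervals within a season are an error.
    """
    if intervals.empty:
        return DailyPattern(pd.Series(dtype=float, index=pd.DatetimeIndex([])), units)
    if "plot_id" in intervals.columns and intervals["plot_id"].nunique() > 1:
        raise ValueError("intervals_to_daily expects a single plot; use groupby upstream")
    iv = intervals.sort_values(["start_date", "end_date"]).reset_index(drop=True)
    if (iv["end_date"] <= iv["start_date"]).any():
        bad = iv[iv["end_date"] <= iv["start_date"]].iloc[0]
        raise ValueError(f"interval with end <= start at {bad['start_date'].date()}")
    # overlap check within a season: (start, end] half-open => abutting is fine
    same_season = iv["start_date"].dt.year == iv["end_date"].dt.year
    for season, grp in iv[same_season].groupby(iv["start_date"].dt.year):
        prev_end = None
        for _, row in grp.iterrows():
            if prev_end is not None and row["start_date"] < prev_end:
                raise ValueError(
                    f"overlapping intervals in season {season}: interval starting "
                    f"{row['start_date'].date()} begins before {prev_end.date()}"
                )
            prev_end = row["end_date"]
    dates, values = [], []
    for _, row in iv.iterrows():
        span = pd.date_range(
            row["start_date"] + pd.Timedelta(days=1), row["end_date"], freq="D"
        )
        dates.append(span)
        values.append(np.full(len(span), float(row["rate_mm_day"])))
    idx = dates[0].append(dates[1:]) if len(dates) > 1 else dates[0]
    return DailyPattern(pd.Series(np.concatenate(values), index=idx).sort_index(), units)


def average_plots(patterns: list[DailyPattern]) -> DailyPattern:
    """Unweighted per-date mean over plots; a date absent from all plots stays absent."""
    if not patterns:
        raise ValueError("need at least one plot pattern")
    units = patterns[0].units
    if any(p.units != units for p in patterns):
        raise ValueError("unit mismatch across plot patterns")
    combined = pd.concat([p.data for p in patterns])
    return DailyPattern(combined.groupby(level=0).mean().sort_index(), units)


def moving_average(pattern: DailyPattern, width: int = 3) -> DailyPattern:
    """Centered moving average computed within each season independently.

    At season edges the window shrinks to the available days, so output
    dates equal input dates.  ``width`` must be odd (a centered window).
    """
    if width < 1 or width % 2 == 0:
        raise ValueError(f"moving-average width must be odd and >= 1, got {width}")
    if width == 1 or len(pattern) == 0:
        return pattern.with_values(pattern.values)
    out = pattern.data.groupby(pattern.season).transform(
        lambda s: s.rolling(width, center=True, min_periods=1).mean()
    )
    return DailyPattern(out, pattern.units, pattern.season.copy())


def daily_kp(kp_3h: pd.Series, aggregator: str = "mean") -> DailyPattern:
    """Reduce the 3-hourly Kp series to one value per complete UTC day.

    Days with fewer than eight slots are dropped with a logged warning.
    The published record does not fix a daily reduction; the default is the
    mean of the eight slots, with ``"max"`` available.
    """
    if aggregator not in ("mean", "max"):
        raise ValueError(f"unknown Kp aggregator {aggregator!r}; use 'mean' or 'max'")
    by_day = kp_3h.groupby(kp_3h.index.normalize())
    counts = by_day.count()
    incomplete = counts[counts != len(CANONICAL_HOURS)]
    if len(incomplete):
        logger.warning(
            "dropping %d incomplete Kp day(s): %s",
            len(incomplete),
            ", ".join(str(d.date()) for d in incomplete.index[:5]),
        )
    agg = by_day.mean() if aggregator == "mean" else by_day.max()
    agg = agg[counts == len(CANONICAL_HOURS)]
    return DailyPattern(agg.sort_index(), "kp")


def lag_align(
    growth: DailyPattern,
    temp: DailyPattern,
    kp: DailyPattern,
    lag: int = 1,
) -> pd.DataFrame:
    """Pair each growth day d with the drivers of day d - lag.

    Returns a DataFrame with columns ``date, growth_rate, temperature, kp``
    sorted by date; a growth day lacking either driver at d - lag is
    dropped (the count is logged).
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    shift = pd.Timedelta(days=lag)
    t = temp.data.copy()
    t.index = t.index + shift
    k = kp.data.copy()
    k.index = k.index + shift
    df = pd.DataFrame(
        {"growth_rate": growth.data, "temperature": t.reindex(growth.dates), "kp": k.reindex(growth.dates)}
    )
    n_dropped = int(df.isna().any(axis=1).sum())
    if n_dropped:
        logger.info("lag_align dropped %d growth day(s) lacking drivers", n_dropped)
    df = df.dropna()
    out = df.reset_index(names="date")
    return out


# ----------------------------------------------------------------------
# Monitoring bookkeeping
# ----------------------------------------------------------------------

@dataclass
class MonitoringSummary:
    """Per-year and pooled campaign bookkeeping."""

    yearly: pd.DataFrame  # indexed by year
    pooled: pd.Series

    COUNT_COLS = (
        "sampling_events",
        "shoots_measured",
        "plot_growth_rates",
        "mire_growth_rates",
    )
    MEAN_COLS = ("mean_sample_size", "mean_interval_days")


def pool_yearly(yearly: pd.DataFrame) -> pd.Series:
    """Pool yearly bookkeeping rows into the campaign-total row.

    Counts are summed; the two per-year means (sample size, sampling
    interval) are pooled as the *unweighted* mean of the yearly means,
    rounded half-up to one decimal.  Plot counts pool to their range.
    """
    if yearly.empty:
        raise ValueError("no yearly rows to pool")
    pooled = {}
    for col in MonitoringSummary.COUNT_COLS:
        if col in yearly:
            pooled[col] = int(yearly[col].sum())
    if "n_plots" in yearly:
        pooled["n_plots_min"] = int(yearly["n_plots"].min())
        pooled["n_plots_max"] = int(yearly["n_plots"].max())
    for col in MonitoringSummary.MEAN_COLS:
        if col in yearly:
            pooled[col] = round_half_up(float(yearly[col].mean()), 1)
    return pd.Series(pooled)


def monitoring_summary(tables: dict[int, pd.DataFrame]) -> MonitoringSummary:
    """Summarise per-year growth-interval tables into the bookkeeping table.

    Per year: sampling events = distinct sampling dates (interval starts
    and ends); shoots measured = total sample sizes over plot records;
    plot growth rates = number of plot-level interval records; mire-area
    growth rates = number of distinct sampling intervals after plot
    averaging; mean sample size / mean interval rounded half-up to 1 dp.
    """
    if not tables:
        raise ValueError("need at least one year of interval records")
    rows = {}
    for year in sorted(tables):
        df = tables[year]
        if df.empty:
            raise ValueError(f"year {year} has zero sampling events")
        dates = pd.concat([df["start_date"], df["end_date"]]).nunique()
        rows[year] = {
            "sampling_events": int(dates),
            "n_plots": int(df["plot_id"].nunique()),
            "shoots_measured": int(df["n_shoots"].sum()),
            "plot_growth_rates": int(len(df)),
            "mire_growth_rates": int(df[["start_date", "end_date"]].drop_duplicates().shape[0]),
            "mean_sample_size": round_half_up(float(df["n_shoots"].mean()), 1),
            "mean_interval_days": round_half_up(
                float((df["end_date"] - df["start_date"]).dt.days.mean()), 1
            ),
        }
    yearly = pd.DataFrame.from_dict(rows, orient="index")
    yearly.index.name = "year"
    return MonitoringSummary(yearly=yearly, pooled=pool_yearly(yearly))
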