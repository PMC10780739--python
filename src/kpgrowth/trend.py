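"""Seasonal detrending.

Two trend models, matching the two seasonal signals in the data:

* a second-order polynomial fitted to each growing season of the growth
  pattern (the seasonal hump induced by the temperature course), and
* a single annual sinusoid (default period 365.3 days) fitted to the
  multi-year temperature pattern by linear least squares on the basis
  ``{1, sin(2*pi*t/P), cos(2*pi*t/P)}``, with a grid scan over candidate
  periods selecting the best period by R^2.

Residuals keep the dates and season labels of their source pattern, so
they feed straight back into the gradient analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .patterns import DailyPattern


def _r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - fitted) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-20 else 0.0
    return 1.0 - ss_res / ss_tot


@dataclass
class QuadraticSeasonTrend:
    """Per-season quadratic fit: value ~ c0 + c1*x + c2*x^2, x = day of season."""

    coef: dict  # season -> (c0, c1, c2)
    r2: dict  # season -> R^2

    def predict(self, pattern: DailyPattern) -> np.ndarray:
        out = np.empty(len(pattern))
        for season, idx in pattern.season.groupby(pattern.season).groups.items():
            c0, c1, c2 = self.coef[season]
            x = (idx - idx[0]).days.to_numpy(dtype=float)
            out[pattern.dates.get_indexer(idx)] = c0 + c1 * x + c2 * x * x
        return out


@dataclass
class HarmonicTrend:
    """Annual sinusoid ``offset + a*sin(2*pi*(t + phase_days)/period)``.

    ``t`` is measured in days since the first date of the fitted series;
    amplitude ``a = hypot(sin_coef, cos_coef)`` and ``phase_days`` is
    normalised to ``[0, period)``.
    """

    period: float
    sin_coef: float
    cos_coef: float
    offset: float
    r2: float

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.sin_coef, self.cos_coef))

    @property
    def phase_days(self) -> float:
        theta = float(np.arctan2(self.cos_coef, self.sin_coef))
        return (theta / (2.0 * np.pi) * self.period) % self.period

    def predict(self, t_days: np.ndarray) -> np.ndarray:
        w = 2.0 * np.pi / self.period
        return self.offset + self.sin_coef * np.sin(w * t_days) + self.cos_coef * np.cos(w * t_days)


def fit_quadratic_per_season(
    pattern: DailyPattern,
) -> tuple[QuadraticSeasonTrend, DailyPattern]:
    """OLS quadratic in day-of-season, fitted to each season independently.

    Returns the fitted trend and the residual pattern (value - trend).
    Every season needs at least 4 days (one more than parameters).
    """
    coef, r2 = {}, {}
    resid = np.empty(len(pattern))
    values = pattern.values
    pos = 0
    for season, grp in pattern.data.groupby(pattern.season):
        n = len(grp)
        if n < 4:
            raise ValueError(f"season {season} has only {n} day(s); need >= 4 for a quadratic")
        x = (grp.index - grp.index[0]).days.to_numpy(dtype=float)
        y = grp.to_numpy(dtype=float)
        # highest degree first from polyfit; store ascending
        c2, c1, c0 = np.polyfit(x, y, 2)
        fitted = c0 + c1 * x + c2 * x * x
        coef[season] = (float(c0), float(c1), float(c2))
        r2[season] = _r_squared(y, fitted)
        resid[pos : pos + n] = y - fitted
        pos += n
    trend = QuadraticSeasonTrend(coef=coef, r2=r2)
    return trend, pattern.with_values(resid, units="residual")


def fit_harmonic(
    pattern: DailyPattern, period: float = 365.3
) -> tuple[HarmonicTrend, DailyPattern]:
    """Fit ``offset + s*sin + c*cos`` at a fixed period by linear least squares."""
    if period <= 0:
        raise ValueError(f"period must be positive, got {period}")
    if len(pattern) < 3:
        raise ValueError("need at least 3 points to fit the harmonic")
    t = (pattern.dates - pattern.dates[0]).days.to_numpy(dtype=float)
    span = t[-1] - t[0]
    if span < period:
        warnings.warn(
            f"series spans {span:.0f} days, less than one period ({period} d); "
            "amplitude and phase are poorly constrained",
            stacklevel=2,
        )
    w = 2.0 * np.pi / period
    X = np.column_stack([np.ones_like(t), np.sin(w * t), np.cos(w * t)])
    y = pattern.values
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    trend = HarmonicTrend(
        period=float(period),
        sin_coef=float(beta[1]),
        cos_coef=float(beta[2]),
        offset=float(beta[0]),
        r2=_r_squared(y, fitted),
    )
    return trend, pattern.with_values(y - fitted, units="residual")


def scan_period(
    pattern: DailyPattern, period_grid
) -> tuple[HarmonicTrend, pd.DataFrame]:
    """Fit every candidate period; return the best-R^2 fit and the scan table.

    Ties resolve to the smaller period.
    """
    grid = [float(p) for p in period_grid]
    if not grid:
        raise ValueError("period grid is empty")
    rows = []
    best = None
    for p in sorted(grid):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit, _ = fit_harmonic(pattern, p)
        rows.append({"period": p, "r2": fit.r2})
        if best is None or fit.r2 > best.r2:
            best = fit
    return best, pd.DataFrame(rows)
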