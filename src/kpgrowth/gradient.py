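"""Growth-temperature correlation along the geomagnetic Kp gradient.

The core analysis: paired daily records (growth rate, day-prior
temperature, day-prior Kp) are sorted by Kp, and the Pearson correlation
between growth and temperature is computed in a sliding window of fixed
size along the sorted sequence.  Each window is summarised by its mean Kp,
so the result is a profile r(Kp) describing how the temperature growth
response changes with geomagnetic activity.  A contiguous run of windows
whose r exceeds a reference level (default: the global r) marks the
"favorable" Kp interval; a permutation null (Kp shuffled against fixed
growth-temperature pairs) calibrates how much profile structure arises by
chance.

P-values use the exact t transform of r with n-2 degrees of freedom and
are kept in log10 space throughout, so the extreme values typical of
thousand-record seasonal series (exponents of -100 and beyond) never
underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import special, stats

LOG10 = np.log(10.0)


def _log10_t_sf(t_abs: float, df: int) -> float:
    """log10 of the Student-t survival function, safe far into the tail.

    Within float range this is ``log10(t.sf)``; deeper, it switches to the
    incomplete-beta representation ``sf = I_x(df/2, 1/2) / 2`` with
    ``x = df/(df + t^2)`` evaluated in log space via a direct
    hypergeometric series, so |t| in the hundreds still yields a finite
    exponent.
    """
    sf = float(stats.t.sf(t_abs, df))
    if sf > 1e-290:
        return np.log(sf) / LOG10
    a, b = df / 2.0, 0.5
    x = df / (df + t_abs * t_abs)
    # 2F1(a + b, 1; a + 1; x) summed directly; ratio -> x < 1 so it converges
    term, s, k = 1.0, 1.0, 0
    while k < 100000:
        term *= x * (a + b + k) / (a + 1.0 + k)
        s += term
        k += 1
        if term <= 1e-17 * s:
            break
    ln_sf = (
        np.log(0.5)
        + a * np.log(x)
        + b * np.log1p(-x)
        - np.log(a)
        - special.betaln(a, b)
        + np.log(s)
    )
    return float(ln_sf / LOG10)


@dataclass
class CorrelationResult:
    """Pearson r with its pair count and two-sided log10 p-value."""

    r: float
    n: int
    log10_p: float

    @property
    def p(self) -> float:
        """The p-value itself (0.0 if it underflows a float)."""
        return 10.0 ** self.log10_p


@dataclass
class KpInterval:
    """A detected Kp interval of elevated growth response."""

    lo: float
    hi: float
    window_indices: np.ndarray = field(default=None)
    r_inside: float | None = None
    n_inside: int | None = None

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError(f"interval lo {self.lo} > hi {self.hi}")


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with a log-space two-sided p-value.

    ``p = 2 * SF(|t|)`` with ``t = r*sqrt((n-2)/(1-r^2))`` on n-2 df,
    evaluated via ``t.logsf`` so |t| > 25 still yields a finite exponent.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(np.sqrt(np.sum(xd * xd)))
    sy = float(np.sqrt(np.sum(yd * yd)))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a constant input")
    r = float(np.clip(np.dot(xd, yd) / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        log10_p = -np.inf  # exact linearity: p vanishes in the limit
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        log10_p = min(0.0, np.log10(2.0) + _log10_t_sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, log10_p=float(log10_p))


def sort_by_kp(records: pd.DataFrame) -> pd.DataFrame:
    """Stable ascending sort on Kp, ties broken by date ascending."""
    if records.empty:
        raise ValueError("no paired records to sort")
    out = records.sort_values("date", kind="stable").sort_values("kp", kind="stable")
    return out.reset_index(drop=True)


def _window_profile(g: np.ndarray, t: np.ndarray, window: int) -> np.ndarray:
    """Pearson r in every length-``window`` slice, computed per window.

    Uses a strided view so each window's r is the exact direct computation
    (no cumulative-sum shortcuts), vectorised over windows.
    """
    gw = sliding_window_view(g, window)
    tw = sliding_window_view(t, window)
    gd = gw - gw.mean(axis=1, keepdims=True)
    td = tw - tw.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", gd, td)
    den = np.sqrt(np.einsum("ij,ij->i", gd, gd) * np.einsum("ij,ij->i", td, td))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def sliding_window_correlation(records: pd.DataFrame, window: int = 200) -> pd.DataFrame:
    """Windowed growth-temperature r along the Kp-sorted record sequence.

    ``records`` must already be sorted by Kp (see :func:`sort_by_kp`).
    Returns one row per window (step 1, ``n - window + 1`` rows) with
    columns ``window_index, kp_mean, kp_median, r, n``.
    """
    n = len(records)
    if window < 3:
        raise ValueError("window must be >= 3")
    if n < window:
        raise ValueError(
            f"{n} records < window of {window}; use a smaller window (e.g. <= {n})"
        )
    g = records["growth_rate"].to_numpy(dtype=float)
    t = records["temperature"].to_numpy(dtype=float)
    kp = records["kp"].to_numpy(dtype=float)
    kw = sliding_window_view(kp, window)
    return pd.DataFrame(
        {
            "window_index": np.arange(n - window + 1),
            "kp_mean": kw.mean(axis=1),
            "kp_median": np.median(kw, axis=1),
            "r": _window_profile(g, t, window),
            "n": window,
        }
    )


def subrange_summary(records: pd.DataFrame, lo: float, hi: float) -> CorrelationResult:
    """Pearson r over all records with Kp in the closed range [lo, hi]."""
    mask = (records["kp"] >= lo) & (records["kp"] <= hi)
    n_in = int(mask.sum())
    if n_in < 3:
        raise ValueError(f"only {n_in} record(s) with Kp in [{lo}, {hi}]; need >= 3")
    sub = records[mask]
    return pearson(sub["growth_rate"], sub["temperature"])


def detect_favorable_interval(
    windows: pd.DataFrame,
    reference_r: float,
    threshold: float | None = None,
    kp_stat: str = "kp_mean",
) -> KpInterval | None:
    """Locate the Kp interval where windowed r sits above a reference level.

    Windows with ``r >= threshold`` (default: the global correlation
    ``reference_r``) are flagged; maximal contiguous runs of flagged
    windows are formed, and the run containing the maximum-r window is
    returned as ``[min kp, max kp]`` over the run's window Kp statistic.
    Returns ``None`` when no window is flagged.
    """
    if windows.empty:
        raise ValueError("no window statistics supplied")
    if kp_stat not in ("kp_mean", "kp_median"):
        raise ValueError(f"kp_stat must be 'kp_mean' or 'kp_median', got {kp_stat!r}")
    thr = reference_r if threshold is None else threshold
    r = windows["r"].to_numpy(dtype=float)
    flagged = r >= thr
    if not flagged.any():
        return None
    # maximal runs of consecutive flagged windows
    idx = np.flatnonzero(flagged)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    best = int(idx[np.argmax(r[idx])])
    run = next(rn for rn in runs if rn[0] <= best <= rn[-1])
    kp_vals = windows[kp_stat].to_numpy(dtype=float)[run]
    return KpInterval(
        lo=float(kp_vals.min()), hi=float(kp_vals.max()), window_indices=run
    )


def fraction_days_in_interval(kp_days, interval: KpInterval) -> float:
    """Percent of monitoring days whose Kp lies in the interval (1 dp)."""
    kp = np.asarray(
        kp_days.values if hasattr(kp_days, "values") else kp_days, dtype=float
    ).ravel()
    if kp.size == 0:
        raise ValueError("empty day set")
    frac = float(np.mean((kp >= interval.lo) & (kp <= interval.hi)))
    return round(100.0 * frac, 1)


def permutation_envelope(
    records: pd.DataFrame,
    window: int = 200,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pointwise null envelope of the windowed-r profile under shuffled Kp.

    The Kp column is permuted against the fixed (growth, temperature)
    pairs ``n_perm`` times; each permutation is re-sorted and its window
    profile recomputed.  Returns per window index the 2.5/50/97.5%
    quantiles plus the observed sorted-Kp ``kp_mean`` for plotting.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    n = len(records)
    if n < window:
        raise ValueError(f"{n} records < window of {window}")
    # date-ascending base order makes the stable argsort tie-break by date
    base = records.sort_values("date", kind="stable")
    g = base["growth_rate"].to_numpy(dtype=float)
    t = base["temperature"].to_numpy(dtype=float)
    kp = base["kp"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    m = n - window + 1
    prof = np.empty((n_perm, m))
    for i in range(n_perm):
        perm_kp = kp[rng.permutation(n)]
        order = np.argsort(perm_kp, kind="stable")
        prof[i] = _window_profile(g[order], t[order], window)
    q = np.nanquantile(prof, [0.025, 0.5, 0.975], axis=0)
    obs_order = np.argsort(kp, kind="stable")
    kw = sliding_window_view(kp[obs_order], window)
    return pd.DataFrame(
        {
            "window_index": np.arange(m),
            "kp_mean": kw.mean(axis=1),
            "q025": q[0],
            "q500": q[1],
            "q975": q[2],
        }
    )
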