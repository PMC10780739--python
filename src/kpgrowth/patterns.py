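"""Core date-indexed containers shared by the pipeline stages.

A :class:`DailyPattern` is the package's basic object: a daily series of
growth rates (mm/day), temperatures (degC), geomagnetic Kp values, or
detrending residuals, labelled by growing season.  Growing seasons never
bridge the winter gap, and several operations (smoothing, detrending) act
strictly within a season.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognised units tags for a DailyPattern.
UNITS = ("mm/day", "degC", "kp", "residual")


@dataclass
class DailyPattern:
    """A date-indexed daily series with a units tag and season labels.

    Parameters
    ----------
    data : pandas.Series
        Values indexed by calendar date (coerced to a ``DatetimeIndex``).
        Dates must be strictly increasing; days with no observation are
        simply absent.
    units : str
        One of ``"mm/day"``, ``"degC"``, ``"kp"``, ``"residual"``.
    season : pandas.Series, optional
        Season identifier per date.  Defaults to the calendar year, which
        is correct for a single April--October growing season per year.
    """

    data: pd.Series
    units: str
    season: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.Series):
            self.data = pd.Series(self.data)
        if not isinstance(self.data.index, pd.DatetimeIndex):
            self.data = self.data.copy()
            self.data.index = pd.DatetimeIndex(pd.to_datetime(self.data.index))
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate date in pattern: {dup.date()}")
        if not self.data.index.is_monotonic_increasing:
            raise ValueError("pattern dates must be strictly increasing")
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {UNITS}")
        if self.season is None:
            self.season = pd.Series(self.data.index.year, index=self.data.index)
        else:
            if not self.season.index.equals(self.data.index):
                raise ValueError("season labels must be indexed by the same dates")

    # -- conveniences -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def with_values(self, values, units: str | None = None) -> "DailyPattern":
        """Return a new pattern with the same dates/seasons but new values."""
        new = pd.Series(np.asarray(values, dtype=float), index=self.data.index)
        return DailyPattern(new, units or self.units, self.season.copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.data.index, "value": self.values, "season": self.season.to_numpy()}
        )
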