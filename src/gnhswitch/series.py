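"""Daily time-series container used throughout the package.

A :class:`DailySeries` is a gap-free run of consecutive calendar days with
one real value per day.  It is a thin, validated wrapper around a
``pandas.DatetimeIndex`` plus a ``numpy`` array; analysis code that does not
care about dates can operate on ``series.values`` directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DailySeries"]


@dataclass(frozen=True)
class DailySeries:
    """Consecutive daily observations of one variable.

    Parameters
    ----------
    dates
        Strictly increasing, gap-free daily ``DatetimeIndex``.
    values
        Finite float values, one per date.
    name
        Label for the variable (used in output headers).
    """

    dates: pd.DatetimeIndex
    values: np.ndarray
    name: str = "value"

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if len(dates) != len(values):
            raise ValueError(
                f"dates ({len(dates)}) and values ({len(values)}) differ in length"
            )
        if len(dates) == 0:
            raise ValueError("series must contain at least one observation")
        diffs = np.diff(dates.asi8)
        one_day = 86_400_000_000_000  # ns
        if np.any(diffs != one_day):
            bad = dates[1:][diffs != one_day]
            raise ValueError(
                "dates must be strictly consecutive calendar days; "
                f"first irregularity at {bad[0].date()}"
            )
        if not np.all(np.isfinite(values)):
            idx = int(np.flatnonzero(~np.isfinite(values))[0])
            raise ValueError(f"non-finite value at {dates[idx].date()}")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def weekdays(self) -> np.ndarray:
        """Integer day of week per observation (Monday=0 .. Sunday=6)."""
        return self.dates.dayofweek.to_numpy()

    def with_values(self, values: np.ndarray, name: str | None = None) -> "DailySeries":
        """Return a copy with the same date axis but new values."""
        return DailySeries(self.dates, values, name or self.name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, self.name: self.values})

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, date_column: str = "date", value_column: str = "value"
    ) -> "DailySeries":
        frame = frame.sort_values(date_column)
        return cls(
            pd.DatetimeIndex(frame[date_column]),
            frame[value_column].to_numpy(dtype=float),
            name=value_column,
        )
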