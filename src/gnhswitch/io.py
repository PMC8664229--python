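"""CSV reading and writing with strict date-axis validation.

All tabular exchange uses CSV with an ISO-8601 ``date`` column.  Reading
is strict: dates must parse, be unique, and form a gap-free run of
calendar days; value cells must be numeric and finite.  Errors name the
offending date or row so malformed inputs fail loudly before any
modelling.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .series import DailySeries

__all__ = [
    "read_daily_csv",
    "read_covariate_csv",
    "write_series_csv",
    "write_table_csv",
]


def _validated_dates(raw: pd.Series, path) -> pd.DatetimeIndex:
    try:
        dates = pd.DatetimeIndex(pd.to_datetime(raw, format="ISO8601"))
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable ISO-8601 date: {exc}") from None
    dup = dates[dates.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate date {dup[0].date()}")
    order = np.argsort(dates.asi8, kind="stable")
    sorted_dates = dates[order]
    full = pd.date_range(sorted_dates[0], sorted_dates[-1], freq="D")
    if len(full) != len(sorted_dates):
        missing = full.difference(sorted_dates)
        shown = ", ".join(str(d.date()) for d in missing[:10])
        more = "" if len(missing) <= 10 else f" (and {len(missing) - 10} more)"
        raise ValueError(f"{path}: missing calendar days: {shown}{more}")
    return dates


def _numeric_column(frame: pd.DataFrame, column: str, path) -> np.ndarray:
    vals = pd.to_numeric(frame[column], errors="coerce")
    bad = vals.isna() & frame[column].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: non-numeric value {frame[column].iloc[row]!r} in column "
            f"{column!r} at data row {row + 1}"
        )
    if vals.isna().any():
        row = int(np.flatnonzero(vals.isna().to_numpy())[0])
        raise ValueError(f"{path}: missing value in column {column!r} at data row {row + 1}")
    return vals.to_numpy(dtype=float)


def read_daily_csv(
    path, date_column: str = "date", value_column: str = "value"
) -> DailySeries:
    """Read one daily series from CSV, enforcing a gap-free date axis."""
    path = Path(path)
    frame = pd.read_csv(path)
    for col in (date_column, value_column):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}; found {list(frame.columns)}")
    dates = _validated_dates(frame[date_column], path)
    values = _numeric_column(frame, value_column, path)
    order = np.argsort(dates.asi8, kind="stable")
    return DailySeries(dates[order], values[order], name=value_column)


def read_covariate_csv(path, date_column: str = "date") -> pd.DataFrame:
    """Read a dated covariate table; all non-date columns must be numeric.

    Returns a frame sorted by date with a validated gap-free ``date``
    column first.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if date_column not in frame.columns:
        raise ValueError(f"{path}: missing column {date_column!r}")
    dates = _validated_dates(frame[date_column], path)
    cols = {"date": dates}
    for col in frame.columns:
        if col == date_column:
            continue
        cols[col] = _numeric_column(frame, col, path)
    out = pd.DataFrame(cols).sort_values("date").reset_index(drop=True)
    return out


def write_series_csv(series: DailySeries, path) -> None:
    frame = pd.DataFrame(
        {"date": series.dates.strftime("%Y-%m-%d"), series.name: series.values}
    )
    frame.to_csv(path, index=False)


def write_table_csv(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    if "date" in out.columns:
        out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
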