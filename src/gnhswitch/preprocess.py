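"""Transformations from raw inputs to the analysis series and covariates.

Covers the standard preparation steps for the happiness-regime analysis:
removal of the average day-of-week cycle, cubic-spline imputation of weekly
administrative figures to a daily grid, a PCA "lack of mobility" index from
the six community-mobility categories, log transforms of count covariates,
and lagging.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.decomposition import PCA

from .series import DailySeries

__all__ = [
    "remove_day_of_week_effect",
    "interpolate_weekly_to_daily",
    "mobility_index",
    "log_transform",
    "inverse_log_transform",
    "lag",
    "MOBILITY_COLUMNS",
]

#: Column order of the six community-mobility categories.
MOBILITY_COLUMNS = (
    "retail_and_recreation",
    "grocery_and_pharmacy",
    "parks",
    "transit_stations",
    "workplaces",
    "residential",
)


def remove_day_of_week_effect(series: DailySeries) -> DailySeries:
    """Subtract each weekday's average deviation from the overall mean.

    ``out[t] = value[t] - (mean over t's weekday - overall mean)``.  The
    adjustment is additive and estimated once on the full sample.  On spans
    of whole weeks the overall mean is preserved and every weekday's mean
    equals it afterwards; applying the operation twice then equals applying
    it once.
    """
    if len(series) < 14:
        raise ValueError("need at least 14 days to estimate a weekday cycle")
    wd = series.weekdays
    counts = np.bincount(wd, minlength=7)
    if np.any(counts < 2):
        short = int(np.flatnonzero(counts < 2)[0])
        raise ValueError(f"fewer than 2 observations for weekday {short} (Mon=0)")
    overall = series.values.mean()
    sums = np.bincount(wd, weights=series.values, minlength=7)
    weekday_means = sums / counts
    adjusted = series.values - (weekday_means[wd] - overall)
    return series.with_values(adjusted, name=f"{series.name}_smoothed")


def interpolate_weekly_to_daily(
    anchor_dates, anchor_values, name: str = "value"
) -> DailySeries:
    """Natural cubic spline through weekly anchors, evaluated every day.

    The interpolant passes through every anchor and has zero second
    derivative at both ends.  At least four anchors are required for the
    cubic pieces to be determined.
    """
    dates = pd.DatetimeIndex(anchor_dates)
    values = np.asarray(anchor_values, dtype=float)
    if len(dates) != len(values):
        raise ValueError("anchor dates and values differ in length")
    if len(dates) < 4:
        raise ValueError("need at least 4 anchors for cubic-spline imputation")
    if not dates.is_monotonic_increasing or dates.has_duplicates:
        raise ValueError("anchor dates must be strictly increasing")
    x = (dates - dates[0]).days.to_numpy(dtype=float)
    spline = CubicSpline(x, values, bc_type="natural")
    daily = pd.date_range(dates[0], dates[-1], freq="D")
    xd = (daily - dates[0]).days.to_numpy(dtype=float)
    return DailySeries(daily, spline(xd), name=name)


def mobility_index(table: pd.DataFrame) -> DailySeries:
    """First principal component of the six mobility categories.

    Columns are standardised to zero mean and unit variance (the categories
    are incommensurate percent changes), so the PCA acts on the correlation
    matrix.  The component's sign is oriented so it correlates positively
    with the residential (stay-at-home) column: higher scores mean more
    "lack of mobility".
    """
    cols = [c for c in MOBILITY_COLUMNS if c in table.columns]
    if len(cols) < 2:
        raise ValueError(
            f"expected mobility columns named like {MOBILITY_COLUMNS}, "
            f"found {list(table.columns)}"
        )
    if len(table) < 10:
        raise ValueError("need at least 10 rows for a stable mobility index")
    X = table[cols].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise ValueError("mobility table contains missing or non-finite values")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = cols[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"mobility column {bad!r} has zero variance")
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=1)
    scores = pca.fit_transform(Z)[:, 0]
    loadings = pca.components_[0]
    if "residential" in cols and loadings[cols.index("residential")] < 0:
        scores = -scores
    elif "residential" not in cols and scores @ Z[:, 0] < 0:
        scores = -scores
    if "date" in table.columns:
        return DailySeries(
            pd.DatetimeIndex(table["date"]), scores, name="mobility_lack"
        )
    idx = pd.DatetimeIndex(table.index) if isinstance(
        table.index, pd.DatetimeIndex
    ) else pd.date_range("2020-01-01", periods=len(scores), freq="D")
    return DailySeries(idx, scores, name="mobility_lack")


def log_transform(series: DailySeries) -> DailySeries:
    """log(1 + x) of a non-negative count series, so zero days map to zero."""
    if np.any(series.values < 0):
        idx = int(np.flatnonzero(series.values < 0)[0])
        raise ValueError(
            f"log transform requires non-negative values; "
            f"negative value at {series.dates[idx].date()}"
        )
    return series.with_values(np.log1p(series.values), name=f"{series.name}_log")


def inverse_log_transform(series: DailySeries) -> DailySeries:
    """Inverse of :func:`log_transform`: exp(x) - 1."""
    return series.with_values(np.expm1(series.values))


def lag(series: DailySeries, k: int = 1) -> DailySeries:
    """Shift values back by ``k`` days: day t carries the value of day t-k.

    The first ``k`` days, which have no lagged value, are dropped.
    """
    if not 0 <= k < len(series):
        raise ValueError(f"lag k={k} must satisfy 0 <= k < {len(series)}")
    if k == 0:
        return series
    return DailySeries(
        series.dates[k:], series.values[:-k], name=f"{series.name}_lag{k}"
    )
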