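"""Pre-fit diagnostics motivating a regime-switching model.

Three classical checks are provided, mirroring the battery run before
fitting the switching model to the happiness index:

* :func:`sup_wald_break` — structural break at an unknown date, taking the
  supremum of heteroscedasticity-robust Wald statistics for a mean shift
  over a trimmed interior of candidate break days, with a parametric
  (Gaussian) bootstrap p-value.
* :func:`mcleod_li` — the ARCH LM test of McLeod-Li type: squared demeaned
  observations regressed on their own lags; both the F and the T*R-squared
  (chi-squared) variants are reported per lag.
* :func:`phillips_perron` — unit-root test with the Bartlett/Newey-West
  long-run variance correction, reporting both the normalised-bias Z_rho
  and the studentised Z_t statistics, with and without a linear trend,
  against interpolated Dickey-Fuller critical values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .series import DailySeries

__all__ = [
    "BreakTestResult",
    "ArchLMRecord",
    "ArchLMResult",
    "PPStatistics",
    "UnitRootResult",
    "sup_wald_break",
    "mcleod_li",
    "phillips_perron",
]


# --- structural break ---------------------------------------------------------

@dataclass(frozen=True)
class BreakTestResult:
    """Supremum-Wald break test output.

    ``candidate_days`` are 1-based day numbers; the break day ``b`` splits
    the sample into days 1..b and b+1..T.
    """

    statistic: float
    break_index: int
    break_date: pd.Timestamp | None
    p_value: float
    candidate_days: np.ndarray
    candidate_stats: np.ndarray
    trim: float


def _supwald_scan(Y: np.ndarray, trim: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise sup-Wald scan over candidate mean-shift break days.

    For each candidate day b the Wald statistic tests the post-break mean
    shift with an HC0-robust variance; with group-dummy regressors that
    variance is the sum of the two group-mean variances, so the whole scan
    reduces to cumulative sums.
    """
    Y = np.atleast_2d(Y)
    T = Y.shape[1]
    lo = int(np.ceil(trim * T))
    hi = int(np.floor((1.0 - trim) * T))
    days = np.arange(lo, hi + 1)  # 1-based break day b
    cs = np.cumsum(Y, axis=1)
    cs2 = np.cumsum(Y * Y, axis=1)
    n1 = days.astype(float)
    n2 = T - n1
    s1 = cs[:, days - 1]
    ss1 = cs2[:, days - 1]
    s2 = cs[:, [-1]] - s1
    ss2 = cs2[:, [-1]] - ss1
    m1, m2 = s1 / n1, s2 / n2
    rss1 = np.maximum(ss1 - n1 * m1 * m1, 0.0)
    rss2 = np.maximum(ss2 - n2 * m2 * m2, 0.0)
    var = rss1 / n1**2 + rss2 / n2**2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(var > 0, (m2 - m1) ** 2 / var, np.inf)
    return days, wald, wald.max(axis=1)


def sup_wald_break(
    series: DailySeries | np.ndarray,
    trim: float = 0.15,
    reps: int = 999,
    seed: int = 0,
) -> BreakTestResult:
    """Test for one mean-shift break at an unknown day.

    The statistic is the maximum over candidate break days (within the
    ``trim`` fraction trimmed interior) of the robust Wald statistic for
    the shift.  The p-value is a parametric bootstrap: ``reps`` Gaussian
    samples are drawn under the no-break null with the sample mean and
    variance, and the tail frequency of their sup-Wald statistics is
    reported with the add-one correction.  The statistic is exactly
    invariant to location and scale, so the bootstrap is exact under
    Gaussianity up to Monte-Carlo error.
    """
    if not 0.0 < trim < 0.5:
        raise ValueError(f"trim must lie strictly between 0 and 0.5, got {trim}")
    dates = series.dates if isinstance(series, DailySeries) else None
    y = series.values if isinstance(series, DailySeries) else np.asarray(series, float)
    T = len(y)
    if T < 30:
        raise ValueError("need at least 30 observations for the break scan")
    if y.std() == 0:
        raise ValueError("series is constant; the break test is undefined")
    days, wald, stat = _supwald_scan(y, trim)
    wald, stat = wald[0], float(stat[0])
    k = int(np.argmax(wald))
    rng = np.random.default_rng(seed)
    boot = rng.standard_normal((reps, T))  # pivotal: location/scale drop out
    _, _, boot_stats = _supwald_scan(boot, trim)
    p = (1.0 + np.sum(boot_stats >= stat)) / (reps + 1.0)
    break_day = int(days[k])
    return BreakTestResult(
        statistic=stat,
        break_index=break_day,
        break_date=dates[break_day - 1] if dates is not None else None,
        p_value=float(p),
        candidate_days=days,
        candidate_stats=wald,
        trim=trim,
    )


# --- ARCH LM (McLeod-Li) ------------------------------------------------------

@dataclass(frozen=True)
class ArchLMRecord:
    lag: int
    f_stat: float
    f_pvalue: float
    lm_stat: float
    lm_pvalue: float
    r_squared: float


@dataclass(frozen=True)
class ArchLMResult:
    records: tuple[ArchLMRecord, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records]).set_index("lag")


def mcleod_li(series: DailySeries | np.ndarray, max_lag: int = 5) -> ArchLMResult:
    """ARCH LM test on squared demeaned observations, lags 1..max_lag.

    For each lag order q, the squares are regressed on an intercept and
    their own first q lags; the joint F statistic and the T*R-squared
    statistic (chi-squared with q degrees of freedom under the null of no
    ARCH) are both reported.
    """
    y = series.values if isinstance(series, DailySeries) else np.asarray(series, float)
    T = len(y)
    if max_lag < 1:
        raise ValueError("max_lag must be at least 1")
    if T <= max_lag + 10:
        raise ValueError(f"series too short ({T}) for max_lag={max_lag}")
    if y.std() == 0:
        raise ValueError("series is constant; the ARCH test is undefined")
    z = (y - y.mean()) ** 2
    records = []
    for q in range(1, max_lag + 1):
        Z = np.column_stack([z[q - j - 1 : T - j - 1] for j in range(q)])
        target = z[q:]
        X = np.column_stack([np.ones(len(target)), Z])
        beta, *_ = np.linalg.lstsq(X, target, rcond=None)
        resid = target - X @ beta
        tss = np.sum((target - target.mean()) ** 2)
        rss = np.sum(resid**2)
        r2 = 1.0 - rss / tss
        n = len(target)
        lm = n * r2
        df_den = n - q - 1
        f = (r2 / q) / ((1.0 - r2) / df_den)
        records.append(
            ArchLMRecord(
                lag=q,
                f_stat=float(f),
                f_pvalue=float(stats.f.sf(f, q, df_den)),
                lm_stat=float(lm),
                lm_pvalue=float(stats.chi2.sf(lm, q)),
                r_squared=float(r2),
            )
        )
    return ArchLMResult(records=tuple(records))


# --- Phillips-Perron ----------------------------------------------------------

# Dickey-Fuller critical values (Fuller 1976, Table 8.5.1/8.5.2 conventions),
# interpolated in sample size.  Rows: n = 25, 50, 100, 250, 500, inf.
_DF_TABLE_N = np.array([25.0, 50.0, 100.0, 250.0, 500.0, np.inf])
_DF_RHO = {
    "c": {
        0.01: [-17.2, -18.9, -19.8, -20.3, -20.5, -20.7],
        0.05: [-12.5, -13.3, -13.7, -14.0, -14.0, -14.1],
        0.10: [-10.2, -10.7, -11.0, -11.2, -11.2, -11.3],
    },
    "ct": {
        0.01: [-22.5, -25.7, -27.4, -28.4, -28.9, -29.5],
        0.05: [-17.9, -19.8, -20.7, -21.3, -21.5, -21.8],
        0.10: [-15.6, -16.8, -17.5, -18.0, -18.1, -18.3],
    },
}
_DF_TAU = {
    "c": {
        0.01: [-3.75, -3.58, -3.51, -3.46, -3.44, -3.43],
        0.05: [-3.00, -2.93, -2.89, -2.88, -2.87, -2.86],
        0.10: [-2.63, -2.60, -2.58, -2.57, -2.57, -2.57],
    },
    "ct": {
        0.01: [-4.38, -4.15, -4.04, -3.99, -3.98, -3.96],
        0.05: [-3.60, -3.50, -3.45, -3.43, -3.42, -3.41],
        0.10: [-3.24, -3.18, -3.15, -3.13, -3.13, -3.12],
    },
}


def _df_crit(table: dict, spec: str, n: int) -> dict[float, float]:
    finite = _DF_TABLE_N[:-1]
    out = {}
    for level, vals in table[spec].items():
        vals = np.asarray(vals)
        if n >= finite[-1]:
            # interpolate toward the asymptotic value in 1/n
            out[level] = float(vals[-1] + (vals[-2] - vals[-1]) * finite[-1] / max(n, 1))
        else:
            out[level] = float(np.interp(n, finite, vals[:-1]))
    return out


@dataclass(frozen=True)
class PPStatistics:
    """Phillips-Perron statistics for one deterministic specification."""

    z_rho: float
    z_t: float
    rho: float
    crit_rho: dict[float, float]
    crit_t: dict[float, float]


@dataclass(frozen=True)
class UnitRootResult:
    trend: PPStatistics
    no_trend: PPStatistics
    lags: int
    nobs: int


def _pp_one_spec(y: np.ndarray, lags: int, with_trend: bool) -> PPStatistics:
    T = len(y)
    yt, ylag = y[1:], y[:-1]
    n = T - 1
    cols = [np.ones(n)]
    if with_trend:
        cols.append(np.arange(1.0, n + 1))
    cols.append(ylag)
    X = np.column_stack(cols)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ yt)
    u = yt - X @ beta
    k = X.shape[1]
    rho = beta[-1]
    s2 = u @ u / (n - k)
    se_rho = np.sqrt(s2 * XtX_inv[-1, -1])
    t_rho = (rho - 1.0) / se_rho
    gamma0 = u @ u / n
    lam2 = gamma0
    for ell in range(1, lags + 1):
        w = 1.0 - ell / (lags + 1.0)
        lam2 += 2.0 * w * (u[ell:] @ u[:-ell]) / n
    lam2 = max(lam2, 1e-300)
    # Hamilton-style corrections; the OLS residual scale cancels out of the
    # second terms, leaving only the (X'X)^-1 element.
    a = XtX_inv[-1, -1]
    z_rho = n * (rho - 1.0) - 0.5 * n**2 * a * (lam2 - gamma0)
    z_t = np.sqrt(gamma0 / lam2) * t_rho - 0.5 * n * (lam2 - gamma0) * np.sqrt(a) / np.sqrt(
        lam2
    )
    spec = "ct" if with_trend else "c"
    return PPStatistics(
        z_rho=float(z_rho),
        z_t=float(z_t),
        rho=float(rho),
        crit_rho=_df_crit(_DF_RHO, spec, n),
        crit_t=_df_crit(_DF_TAU, spec, n),
    )


def default_pp_lags(T: int) -> int:
    """Newey-West truncation rule floor(4 * (T/100)^(2/9))."""
    return int(np.floor(4.0 * (T / 100.0) ** (2.0 / 9.0)))


def phillips_perron(
    series: DailySeries | np.ndarray, lags: int | None = None
) -> UnitRootResult:
    """Phillips-Perron unit-root test.

    Fits the first-order autoregression ``y_t = c (+ d t) + rho y_{t-1} + u_t``
    and corrects the normalised-bias statistic ``n (rho - 1)`` (Z_rho) and
    the t statistic (Z_t) for serial correlation in ``u`` with a Bartlett
    long-run variance at truncation ``lags``.  Both the with-trend and
    without-trend specifications are computed on the identical sample.  At
    ``lags=0`` the correction vanishes and Z_t is exactly the Dickey-Fuller
    t statistic.
    """
    y = series.values if isinstance(series, DailySeries) else np.asarray(series, float)
    T = len(y)
    if T < 25:
        raise ValueError("need at least 25 observations for the unit-root test")
    if lags is None:
        lags = default_pp_lags(T)
    if lags < 0 or lags >= T / 2:
        raise ValueError(f"lags={lags} must satisfy 0 <= lags < T/2")
    return UnitRootResult(
        trend=_pp_one_spec(y, lags, with_trend=True),
        no_trend=_pp_one_spec(y, lags, with_trend=False),
        lags=int(lags),
        nobs=T - 1,
    )
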