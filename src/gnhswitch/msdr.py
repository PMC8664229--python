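"""Two-state (generally S-state) Markov-switching dynamic regression.

The observation model is ``y_t = mu_{s_t} + e_t`` with ``e_t ~ N(0,
sigma_{s_t}^2)`` and a latent first-order Markov chain ``s_t``.  Because
the model is dynamic rather than autoregressive, the level adjusts
immediately when the chain switches state — appropriate for a
high-frequency mood index that jumps with events rather than drifting.

Estimation is by EM: the E-step runs the Hamilton filter and Kim smoother,
the M-step has closed forms (smoothed-weighted means and variances, and
expected transition counts for the matrix).  The initial distribution is
tied to the stationary distribution of the transition matrix, so a
two-state fit has exactly six free parameters: two means, two volatilities
and two persistence probabilities.  Robust (sandwich) standard errors are
computed on a working parameterisation (log sigma, logit persistence) and
mapped back by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from . import _engine
from .series import DailySeries
from .simulate import MSDRParameters, stationary_distribution

__all__ = [
    "MSDRFit",
    "FilterUnderflowError",
    "DegenerateStateError",
    "SingularHessianError",
    "hamilton_filter",
    "kim_smooth",
    "fit_msdr",
    "one_step_state_predictions",
    "expected_durations",
    "robust_standard_errors",
    "information_criteria",
    "classify_days",
    "variance_comparison",
    "VarianceComparisonResult",
]


class FilterUnderflowError(FloatingPointError):
    """Every state's density underflowed at some observation."""


class DegenerateStateError(RuntimeError):
    """A state's total smoothed weight fell below one observation."""


class SingularHessianError(np.linalg.LinAlgError):
    """The observed information is singular (e.g. identical states)."""


def _as_values(y) -> np.ndarray:
    if isinstance(y, DailySeries):
        return y.values
    return np.asarray(y, dtype=float)


def hamilton_filter(
    y, params: MSDRParameters
) -> tuple[np.ndarray, np.ndarray, float]:
    """Forward filter: state probabilities given data up to each day.

    Returns ``(filtered, predicted, loglik)`` where ``filtered[t]`` is
    ``P(s_t | y_1..y_t)``, ``predicted[t]`` is ``P(s_t | y_1..y_{t-1})``
    (first row equals the initial distribution) and ``loglik`` is the exact
    log-likelihood of the sample under ``params``.
    """
    yv = _as_values(y)
    if len(yv) < 2:
        raise ValueError("need at least 2 observations")
    if not np.all(np.isfinite(yv)):
        raise ValueError("y contains non-finite values")
    filtered, predicted, logc, err = _engine.filter_pass(
        yv, params.means, params.sigmas, params.transition, params.initial
    )
    if err >= 0:
        raise FilterUnderflowError(
            f"all state densities underflowed at observation t={err}; "
            "the model is grossly misspecified for this datum"
        )
    return filtered, predicted, float(logc.sum())


def kim_smooth(
    filtered: np.ndarray, predicted: np.ndarray, transition: np.ndarray
) -> np.ndarray:
    """Backward smoother: state probabilities given the full sample."""
    filtered = np.asarray(filtered, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    P = np.asarray(transition, dtype=float)
    if filtered.shape != predicted.shape or filtered.shape[1] != P.shape[0]:
        raise ValueError("inconsistent shapes between filter output and transition")
    if np.any(np.abs(filtered.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("filtered rows must sum to 1")
    smoothed, err = _engine.smooth_pass(filtered, predicted, P)
    if err >= 0:
        raise FilterUnderflowError(
            f"zero predicted probability at t={err} blocks the smoother"
        )
    return smoothed


def expected_durations(transition: np.ndarray) -> np.ndarray:
    """Expected sojourn in each state, ``D_i = 1 / (1 - P[i, i])`` days.

    An absorbing state (``p_ii = 1``) yields ``inf`` rather than an error.
    """
    P = np.atleast_2d(np.asarray(transition, dtype=float))
    diag = np.diag(P)
    with np.errstate(divide="ignore"):
        return np.where(diag < 1.0, 1.0 / (1.0 - diag), np.inf)


def information_criteria(loglik: float, k: int, T: int) -> tuple[float, float]:
    """AIC = -2 loglik + 2k and BIC = -2 loglik + k ln T."""
    if T < 1 or k < 1:
        raise ValueError("k and T must be positive")
    return -2.0 * loglik + 2.0 * k, -2.0 * loglik + k * np.log(T)


@dataclass(frozen=True)
class MSDRFit:
    """Fitted Markov-switching model with state-probability tables.

    States are ordered by ascending mean; for two states the labels are
    ``("unhappy", "happy")``.  ``predicted`` holds the one-step-ahead
    probabilities xi_{t|t-1}, ``filtered`` xi_{t|t} and ``smoothed``
    xi_{t|T}.
    """

    params: MSDRParameters
    robust_se: dict[str, np.ndarray] | None
    loglik: float
    n_iter: int
    converged: bool
    filtered: np.ndarray
    predicted: np.ndarray
    smoothed: np.ndarray
    aic: float
    bic: float
    durations: np.ndarray
    duration_se: np.ndarray | None
    labels: tuple[str, ...]
    y: np.ndarray
    dates: pd.DatetimeIndex | None

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_params(self) -> int:
        S = self.params.n_states
        return 2 * S + S * (S - 1)

    def summary(self) -> str:
        p = self.params
        lines = [
            f"Markov-switching dynamic regression, {p.n_states} states, "
            f"T={self.n_obs}",
            f"log-likelihood {self.loglik:.3f}  AIC {self.aic:.2f}  "
            f"BIC {self.bic:.2f}  ({self.n_iter} EM iterations, "
            f"{'converged' if self.converged else 'NOT converged'})",
        ]
        se = self.robust_se
        for i, lab in enumerate(self.labels):
            mu_se = f" ({se['means'][i]:.4f})" if se else ""
            sg_se = f" ({se['sigmas'][i]:.4f})" if se else ""
            ps_se = f" ({se['p_stay'][i]:.4f})" if se else ""
            lines.append(
                f"  {lab:>8}: mean {p.means[i]:.4f}{mu_se}  "
                f"sigma {p.sigmas[i]:.4f}{sg_se}  "
                f"p_stay {p.transition[i, i]:.4f}{ps_se}  "
                f"duration {self.durations[i]:.2f} days"
            )
        return "\n".join(lines)


def _relabel_ascending(
    means: np.ndarray, sigmas: np.ndarray, P: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    order = np.argsort(means, kind="stable")
    return order, means[order], sigmas[order], P[np.ix_(order, order)]


def _initial_starts(
    y: np.ndarray, n_states: int, n_starts: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    sd = y.std(ddof=1)
    qs = np.linspace(0.0, 1.0, n_states + 2)[1:-1]
    # for two states these are the 25th/75th percentiles shifted to 1/3, 2/3;
    # use the conventional quartiles in the two-state case
    if n_states == 2:
        qs = np.array([0.25, 0.75])
    base_means = np.quantile(y, qs)
    base_P = np.full((n_states, n_states), 0.1 / max(n_states - 1, 1))
    np.fill_diagonal(base_P, 0.9)
    starts = [(base_means.copy(), np.full(n_states, sd), base_P.copy())]
    for _ in range(n_starts - 1):
        means = np.sort(base_means + 0.5 * sd * rng.standard_normal(n_states))
        sigmas = np.full(n_states, sd) * np.exp(0.3 * rng.standard_normal(n_states))
        p_stay = expit(logit(0.9) + 0.7 * rng.standard_normal(n_states))
        P = np.empty((n_states, n_states))
        for i in range(n_states):
            off = (1.0 - p_stay[i]) / max(n_states - 1, 1)
            P[i, :] = off
            P[i, i] = p_stay[i]
        starts.append((means, sigmas, P))
    return starts


def fit_msdr(
    y,
    n_states: int = 2,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_starts: int = 5,
    seed: int = 0,
    compute_se: bool = True,
) -> MSDRFit:
    """Fit the switching model by EM from multiple seeded starts.

    The first start places the state means at sample quantiles with a
    common volatility and persistence 0.9; the remaining ``n_starts - 1``
    are random perturbations.  The best final log-likelihood wins.  States
    are relabelled so means ascend, and for two states robust sandwich
    standard errors are attached (set ``compute_se=False`` to skip them,
    e.g. inside simulation loops).
    """
    dates = y.dates if isinstance(y, DailySeries) else None
    yv = _as_values(y)
    T = len(yv)
    if T < 10 * n_states:
        raise ValueError(f"need at least {10 * n_states} observations")
    if yv.std(ddof=1) == 0:
        raise ValueError("series has zero variance")
    rng = np.random.default_rng(seed)
    sigma_floor = 1e-6 * yv.std(ddof=1)
    best = None
    for means0, sigmas0, P0 in _initial_starts(yv, n_states, n_starts, rng):
        means, sigmas, P, ll_hist, n_iter, converged, code, loc = _engine.em_run(
            yv, means0, sigmas0, P0, tol, max_iter, sigma_floor
        )
        if code == _engine.EM_DEGENERATE:
            continue
        if code == _engine.EM_UNDERFLOW:
            continue
        ll = float(ll_hist[-1])
        if best is None or ll > best[0]:
            best = (ll, means, sigmas, P, n_iter, converged)
    if best is None:
        raise DegenerateStateError(
            "every EM start collapsed a state below one observation of weight"
        )
    _, means, sigmas, P, n_iter, converged = best
    _, means, sigmas, P = _relabel_ascending(means, sigmas, P)
    params = MSDRParameters(means=means, sigmas=sigmas, transition=P)
    filtered, predicted, loglik = hamilton_filter(yv, params)
    smoothed = kim_smooth(filtered, predicted, P)
    k = 2 * n_states + n_states * (n_states - 1)
    aic, bic = information_criteria(loglik, k, T)
    durations = expected_durations(P)
    robust_se = duration_se = None
    if compute_se and n_states == 2:
        try:
            robust_se = robust_standard_errors(yv, params)
            p_stay = np.diag(P)
            duration_se = robust_se["p_stay"] / (1.0 - p_stay) ** 2
        except SingularHessianError:
            robust_se = None
    if n_states == 2:
        labels = ("unhappy", "happy")
    else:
        labels = tuple(f"state_{i + 1}" for i in range(n_states))
    return MSDRFit(
        params=params,
        robust_se=robust_se,
        loglik=loglik,
        n_iter=n_iter,
        converged=converged,
        filtered=filtered,
        predicted=predicted,
        smoothed=smoothed,
        aic=aic,
        bic=bic,
        durations=durations,
        duration_se=duration_se,
        labels=labels,
        y=yv,
        dates=dates,
    )


def one_step_state_predictions(fit: MSDRFit) -> pd.DataFrame:
    """Per-day one-step-ahead state probabilities xi_{t|t-1}.

    Row t uses data strictly before day t; the first row is the initial
    (stationary) distribution.
    """
    if not isinstance(fit, MSDRFit):
        raise TypeError("one_step_state_predictions requires a fitted MSDRFit")
    frame = pd.DataFrame(fit.predicted, columns=list(fit.labels))
    if fit.dates is not None:
        frame.index = fit.dates
    return frame


def classify_days(fit: MSDRFit) -> np.ndarray:
    """Most probable state per day from the smoothed probabilities.

    Exact ties go to the higher-mean (happier) state.
    """
    sm = fit.smoothed
    S = sm.shape[1]
    # argmax over reversed columns picks the highest-index state on ties;
    # states are mean-ordered, so ties resolve to the happier state
    idx = S - 1 - np.argmax(sm[:, ::-1], axis=1)
    return np.asarray(fit.labels)[idx]


@dataclass(frozen=True)
class VarianceComparisonResult:
    f_stat: float
    df: tuple[int, int]
    p_value: float
    groups: tuple[str, str]


def variance_comparison(y, labels) -> VarianceComparisonResult:
    """Two-sided variance-ratio F test between two state-classified groups.

    ``F = s_1^2 / s_2^2`` with the numerator group the first distinct label
    in order of appearance, referred to F(n1-1, n2-1).
    """
    yv = _as_values(y)
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, found {len(uniq)}")
    g1 = yv[labels == uniq[0]]
    g2 = yv[labels == uniq[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 observations")
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    if v1 == 0 or v2 == 0:
        raise ValueError("a group has zero variance; the F ratio is undefined")
    f = v1 / v2
    d1, d2 = len(g1) - 1, len(g2) - 1
    p = 2.0 * min(stats.f.sf(f, d1, d2), stats.f.cdf(f, d1, d2))
    return VarianceComparisonResult(
        f_stat=float(f),
        df=(d1, d2),
        p_value=float(min(p, 1.0)),
        groups=(str(uniq[0]), str(uniq[1])),
    )


# --- robust standard errors ---------------------------------------------------

def _theta_pack(params: MSDRParameters) -> np.ndarray:
    P = params.transition
    return np.array(
        [
            params.means[0],
            params.means[1],
            np.log(params.sigmas[0]),
            np.log(params.sigmas[1]),
            logit(P[0, 0]),
            logit(P[1, 1]),
        ]
    )


def _theta_contribs(theta: np.ndarray, y: np.ndarray) -> np.ndarray:
    means = theta[:2].copy()
    sigmas = np.exp(theta[2:4])
    p11, p22 = expit(theta[4]), expit(theta[5])
    P = np.array([[p11, 1.0 - p11], [1.0 - p22, p22]])
    denom = (1.0 - p11) + (1.0 - p22)
    pi = np.array([(1.0 - p22) / denom, (1.0 - p11) / denom])
    _, _, logc, err = _engine.filter_pass(y, means, sigmas, P, pi)
    if err >= 0:
        raise FilterUnderflowError(f"density underflow at t={err}")
    return logc


def robust_standard_errors(y, params: MSDRParameters) -> dict[str, np.ndarray]:
    """Sandwich standard errors for a two-state fit.

    On the working scale (means, log sigmas, logit persistences, with the
    initial distribution tied to the stationary one) the covariance is
    ``H^-1 S H^-1``: ``H`` the numerical observed information and ``S`` the
    outer product of per-day numerical score contributions.  Standard
    errors are mapped back to the natural scale by the delta method.
    """
    yv = _as_values(y)
    if params.n_states != 2:
        raise NotImplementedError("robust SEs are implemented for 2-state fits")
    theta = _theta_pack(params)
    h = 1e-5 * (1.0 + np.abs(theta))
    K = len(theta)
    T = len(yv)
    # per-observation scores by central differences
    G = np.empty((T, K))
    for j in range(K):
        e = np.zeros(K)
        e[j] = h[j]
        G[:, j] = (_theta_contribs(theta + e, yv) - _theta_contribs(theta - e, yv)) / (
            2.0 * h[j]
        )
    S_mat = G.T @ G
    # observed information by central second differences of the total loglik
    def f(th: np.ndarray) -> float:
        return float(_theta_contribs(th, yv).sum())

    H = np.empty((K, K))
    f0 = f(theta)
    for j in range(K):
        ej = np.zeros(K)
        ej[j] = h[j]
        H[j, j] = (f(theta + ej) - 2.0 * f0 + f(theta - ej)) / h[j] ** 2
        for k in range(j + 1, K):
            ek = np.zeros(K)
            ek[k] = h[k]
            H[j, k] = H[k, j] = (
                f(theta + ej + ek)
                - f(theta + ej - ek)
                - f(theta - ej + ek)
                + f(theta - ej - ek)
            ) / (4.0 * h[j] * h[k])
    info = -H
    eigvals = np.linalg.eigvalsh(info)
    if eigvals.min() <= 0 or eigvals.max() / eigvals.min() > 1e12:
        raise SingularHessianError(
            "observed information is singular or near-singular "
            "(states may be indistinguishable)"
        )
    info_inv = np.linalg.inv(info)
    cov = info_inv @ S_mat @ info_inv
    se_theta = np.sqrt(np.diag(cov))
    p_stay = np.diag(params.transition)
    return {
        "means": se_theta[:2],
        "sigmas": params.sigmas * se_theta[2:4],
        "p_stay": p_stay * (1.0 - p_stay) * se_theta[4:6],
    }
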