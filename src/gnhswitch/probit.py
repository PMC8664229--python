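"""Probit model of the probability of being in the happy state.

The binary outcome is "the index is at or above its full-sample mean"
(about 7.13 index points for the study window), and the covariates are the
pandemic indicators: lagged daily cases, border arrivals, jobseeker
payments and the lack-of-mobility index.  Estimation is maximum likelihood
by Newton-Raphson with step-halving; inference uses the Huber-White
sandwich, matching the robust standard errors reported for the published
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .series import DailySeries

__all__ = [
    "ProbitFit",
    "SeparationError",
    "make_binary_outcome",
    "fit_probit",
    "predict_prob",
]


class SeparationError(RuntimeError):
    """Perfect or quasi-separation: a coefficient diverges."""


def make_binary_outcome(
    series: DailySeries | np.ndarray, threshold: float | None = None
) -> np.ndarray:
    """1 where value >= threshold, else 0.

    The default threshold is the series' full-sample mean — the cut that
    separates the happy from the unhappy regime in the published analysis.
    """
    y = series.values if isinstance(series, DailySeries) else np.asarray(series, float)
    if len(y) == 0:
        raise ValueError("series is empty")
    if threshold is None:
        threshold = float(y.mean())
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return (y >= threshold).astype(np.int64)


@dataclass(frozen=True)
class ProbitFit:
    """Probit MLE: intercept-first coefficients with sandwich SEs."""

    coefficients: np.ndarray
    robust_se: np.ndarray
    hessian_se: np.ndarray
    loglik: float
    n: int
    n_iter: int
    converged: bool
    feature_names: tuple[str, ...]

    def summary(self) -> str:
        lines = [
            f"Probit fit, n={self.n}, log-likelihood {self.loglik:.3f} "
            f"({self.n_iter} Newton iterations)"
        ]
        names = ("const",) + self.feature_names
        for name, b, se in zip(names, self.coefficients, self.robust_se):
            z = b / se
            p = 2.0 * stats.norm.sf(abs(z))
            lines.append(f"  {name:>20}: {b:+.6g}  ({se:.3g})  p={p:.3g}")
        return "\n".join(lines)


def _design(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        names = tuple(str(c) for c in X.columns)
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        if mat.ndim != 2:
            raise ValueError("X must be 1- or 2-dimensional")
        names = tuple(f"x{i}" for i in range(mat.shape[1]))
    return mat, names


def _probit_parts(eta: np.ndarray, y: np.ndarray):
    """Generalised residual r, Newton weight w, and loglik for probit."""
    # stable inverse Mills ratios via log pdf/cdf
    log_pdf = stats.norm.logpdf(eta)
    lam1 = np.exp(log_pdf - stats.norm.logcdf(eta))  # phi/Phi(eta)
    lam0 = np.exp(log_pdf - stats.norm.logcdf(-eta))  # phi/Phi(-eta)
    r = np.where(y == 1, lam1, -lam0)
    w = np.where(y == 1, lam1 * (lam1 + eta), lam0 * (lam0 - eta))
    ll = np.sum(np.where(y == 1, stats.norm.logcdf(eta), stats.norm.logcdf(-eta)))
    return r, np.maximum(w, 1e-12), float(ll)


def fit_probit(X, y, robust: bool = True, max_iter: int = 100, gtol: float = 1e-8) -> ProbitFit:
    """Probit maximum likelihood with an intercept.

    Newton-Raphson on the exact (observed) Hessian with step-halving;
    convergence when the gradient max-norm falls below ``gtol``.  With
    ``robust`` (default) the reported ``robust_se`` is the Huber-White
    sandwich; the inverse-Hessian SEs are always available as
    ``hessian_se``.
    """
    Xmat, names = _design(X)
    y = np.asarray(y)
    n, k = Xmat.shape
    if len(y) != n:
        raise ValueError("X and y differ in length")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome contains a single class; probit is undefined")
    if n <= k + 2:
        raise ValueError(f"too few observations (n={n}) for {k + 1} coefficients")
    # optimise on a standardised design (affine-equivariant, so estimates are
    # unchanged after mapping back, but the gradient tolerance is scale-free)
    centre = Xmat.mean(axis=0)
    spread = Xmat.std(axis=0)
    spread[spread == 0] = 1.0
    Z = np.column_stack([np.ones(n), (Xmat - centre) / spread])
    scale = np.maximum(np.abs(Z).max(axis=0), 1e-12)
    beta = np.zeros(k + 1)
    beta[0] = stats.norm.ppf(np.clip(y.mean(), 1e-10, 1 - 1e-10))
    eta = Z @ beta
    r, w, ll = _probit_parts(eta, y)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        grad = Z.T @ r
        if np.max(np.abs(grad)) < gtol:
            converged = True
            break
        H = (Z * w[:, None]).T @ Z
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular Hessian at iteration {n_iter}") from exc
        # step-halving keeps the likelihood ascending
        for half in range(60):
            cand = beta + step
            eta_c = Z @ cand
            if np.max(np.abs(eta_c)) > 1e4:
                step *= 0.5
                continue
            r_c, w_c, ll_c = _probit_parts(eta_c, y)
            if ll_c >= ll - 1e-12:
                beta, eta, r, w, ll = cand, eta_c, r_c, w_c, ll_c
                break
            step *= 0.5
        else:
            offender = names[int(np.argmax(np.abs(beta[1:] * scale[1:]))) ]
            raise SeparationError(
                "step-halving exhausted with a diverging coefficient; "
                f"covariate {offender!r} likely separates the outcome"
            )
        if np.max(np.abs(eta)) > 40 and np.max(np.abs(grad)) > 1e-4:
            offender = names[int(np.argmax(np.abs(beta[1:] * scale[1:])))]
            raise SeparationError(
                f"coefficient on {offender!r} diverges: perfect or "
                "quasi-separation in the data"
            )
    H = (Z * w[:, None]).T @ Z
    H_inv = np.linalg.inv(H)
    cov_h = H_inv
    if robust:
        B = (Z * (r**2)[:, None]).T @ Z
        cov_r = H_inv @ B @ H_inv
    else:
        cov_r = cov_h
    # map back to the raw covariate scale: beta_raw = A @ beta_std
    A = np.zeros((k + 1, k + 1))
    A[0, 0] = 1.0
    A[0, 1:] = -centre / spread
    A[np.arange(1, k + 1), np.arange(1, k + 1)] = 1.0 / spread
    beta = A @ beta
    hessian_se = np.sqrt(np.diag(A @ cov_h @ A.T))
    robust_se = np.sqrt(np.diag(A @ cov_r @ A.T))
    return ProbitFit(
        coefficients=beta,
        robust_se=robust_se,
        hessian_se=hessian_se,
        loglik=ll,
        n=n,
        n_iter=n_iter,
        converged=converged,
        feature_names=names,
    )


def predict_prob(fit: ProbitFit, X) -> np.ndarray:
    """Phi(a0 + a'x) per row of X, in the open interval (0, 1)."""
    Xmat, names = _design(X)
    if isinstance(X, pd.DataFrame) and names != fit.feature_names:
        raise ValueError(
            f"column mismatch: fit used {fit.feature_names}, got {names}"
        )
    if Xmat.shape[1] != len(fit.coefficients) - 1:
        raise ValueError(
            f"expected {len(fit.coefficients) - 1} columns, got {Xmat.shape[1]}"
        )
    eta = fit.coefficients[0] + Xmat @ fit.coefficients[1:]
    p = stats.norm.cdf(eta)
    tiny = np.finfo(float).tiny
    return np.clip(p, tiny, 1.0 - tiny)
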