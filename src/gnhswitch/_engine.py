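"""Numba kernels for the Markov-switching filter, smoother and EM loop.

These are internal: they work on bare arrays, signal failures through
integer codes instead of exceptions, and leave validation and relabelling
to :mod:`gnhswitch.msdr`.  All recursions are written scalar-wise so numba
compiles them to tight loops; the log-density is max-shifted before
exponentiation so the filter survives observations far in the tails.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG2PI = float(np.log(2.0 * np.pi))

# failure codes returned by em_run
EM_OK = 0
EM_UNDERFLOW = 1
EM_DEGENERATE = 2


@njit(cache=True)
def stationary_power(P):
    """Stationary distribution by power iteration (assumes ergodicity)."""
    S = P.shape[0]
    pi = np.full(S, 1.0 / S)
    for _ in range(20000):
        new = pi @ P
        diff = np.abs(new - pi).max()
        pi = new
        if diff < 1e-15:
            break
    return pi / pi.sum()


@njit(cache=True)
def filter_pass(y, means, sigmas, P, pi):
    """Hamilton filter.

    Returns (filtered, predicted, logc, err_t) where ``logc[t]`` is the log
    one-step normaliser (so ``logc.sum()`` is the log-likelihood) and
    ``err_t`` is -1 on success or the first index where every state's
    density underflowed to zero.
    """
    T = y.shape[0]
    S = means.shape[0]
    filtered = np.zeros((T, S))
    predicted = np.zeros((T, S))
    logc = np.zeros(T)
    pred = pi.copy()
    logd = np.empty(S)
    w = np.empty(S)
    for t in range(T):
        for s in range(S):
            z = (y[t] - means[s]) / sigmas[s]
            logd[s] = -0.5 * z * z - np.log(sigmas[s]) - 0.5 * _LOG2PI
        maxl = -np.inf
        for s in range(S):
            if pred[s] > 0.0 and logd[s] > maxl:
                maxl = logd[s]
        c = 0.0
        for s in range(S):
            w[s] = pred[s] * np.exp(logd[s] - maxl) if pred[s] > 0.0 else 0.0
            c += w[s]
        if not (c > 0.0) or not np.isfinite(c):
            return filtered, predicted, logc, t
        for s in range(S):
            filtered[t, s] = w[s] / c
            predicted[t, s] = pred[s]
        logc[t] = np.log(c) + maxl
        if t < T - 1:
            for j in range(S):
                acc = 0.0
                for i in range(S):
                    acc += P[i, j] * filtered[t, i]
                pred[j] = acc
    return filtered, predicted, logc, -1


@njit(cache=True)
def smooth_pass(filtered, predicted, P):
    """Kim smoother: backward recursion from the filtered probabilities.

    Returns (smoothed, err_t); ``err_t`` is -1 on success or the index of a
    zero predicted probability that would require dividing by zero.
    """
    T, S = filtered.shape
    sm = np.zeros((T, S))
    for s in range(S):
        sm[T - 1, s] = filtered[T - 1, s]
    for t in range(T - 2, -1, -1):
        tot = 0.0
        for i in range(S):
            acc = 0.0
            for j in range(S):
                if predicted[t + 1, j] <= 0.0:
                    if P[i, j] * sm[t + 1, j] > 0.0:
                        return sm, t + 1
                    continue
                acc += P[i, j] * sm[t + 1, j] / predicted[t + 1, j]
            sm[t, i] = filtered[t, i] * acc
            tot += sm[t, i]
        for i in range(S):
            sm[t, i] /= tot
    return sm, -1


@njit(cache=True)
def em_run(y, means0, sigmas0, P0, tol, max_iter, sigma_floor):
    """EM for the Gaussian Markov-switching mean/variance model.

    The initial distribution is tied to the stationary distribution of the
    current transition matrix at every iteration (it is not a free
    parameter), which makes the closed-form M-step a generalised rather
    than exact EM update; a guard therefore rejects any update that lowers
    the tied likelihood and stops there, so the recorded trace is monotone.
    Returns the updated parameters, the log-likelihood trace evaluated at
    the start of each iteration, the iteration count, a convergence flag
    and a failure code with its location.
    """
    T = y.shape[0]
    S = means0.shape[0]
    means = means0.copy()
    sigmas = sigmas0.copy()
    P = P0.copy()
    prev_means = means.copy()
    prev_sigmas = sigmas.copy()
    prev_P = P.copy()
    ll_hist = np.empty(max_iter)
    n_iter = 0
    converged = False
    for it in range(max_iter):
        pi = stationary_power(P)
        filtered, predicted, logc, err = filter_pass(y, means, sigmas, P, pi)
        if err >= 0:
            return means, sigmas, P, ll_hist[:n_iter], n_iter, False, EM_UNDERFLOW, err
        ll = logc.sum()
        if it > 0 and ll < ll_hist[it - 1]:
            # the tied-pi M-step overshot: revert and stop at the ascent point
            means = prev_means.copy()
            sigmas = prev_sigmas.copy()
            P = prev_P.copy()
            converged = True
            break
        ll_hist[it] = ll
        n_iter = it + 1
        if it > 0 and ll - ll_hist[it - 1] < tol * abs(ll_hist[it - 1]):
            converged = True
            break
        sm, serr = smooth_pass(filtered, predicted, P)
        if serr >= 0:
            return means, sigmas, P, ll_hist[:n_iter], n_iter, False, EM_UNDERFLOW, serr
        prev_means = means.copy()
        prev_sigmas = sigmas.copy()
        prev_P = P.copy()
        # expected transitions i -> j
        num = np.zeros((S, S))
        for t in range(T - 1):
            for i in range(S):
                for j in range(S):
                    if predicted[t + 1, j] > 0.0:
                        num[i, j] += (
                            filtered[t, i] * P[i, j] * sm[t + 1, j] / predicted[t + 1, j]
                        )
        for i in range(S):
            tot = 0.0
            for j in range(S):
                tot += num[i, j]
            if tot > 0.0:
                for j in range(S):
                    P[i, j] = num[i, j] / tot
        for s in range(S):
            wsum = 0.0
            for t in range(T):
                wsum += sm[t, s]
            if wsum < 1.0:
                return means, sigmas, P, ll_hist[:n_iter], n_iter, False, EM_DEGENERATE, s
            m = 0.0
            for t in range(T):
                m += sm[t, s] * y[t]
            m /= wsum
            v = 0.0
            for t in range(T):
                d = y[t] - m
                v += sm[t, s] * d * d
            v /= wsum
            means[s] = m
            sigmas[s] = max(np.sqrt(v), sigma_floor)
    return means, sigmas, P, ll_hist[:n_iter], n_iter, converged, EM_OK, -1
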