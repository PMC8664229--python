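"""Independent numerical oracles shared across test modules.

These deliberately re-derive results from first principles (tridiagonal
natural-spline solve, eigendecomposition PCA) so they share no code with
the implementations they check.
"""

import numpy as np


def natural_spline_oracle(x, y, xq):
    """Natural cubic spline through (x, y) evaluated at xq, by a direct
    solve of the second-derivative system with free ends."""
    n = len(x)
    h = np.diff(x)
    A = np.zeros((n, n))
    b = np.zeros(n)
    A[0, 0] = A[-1, -1] = 1.0
    for i in range(1, n - 1):
        A[i, i - 1] = h[i - 1] / 6.0
        A[i, i] = (h[i - 1] + h[i]) / 3.0
        A[i, i + 1] = h[i] / 6.0
        b[i] = (y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1]
    M = np.linalg.solve(A, b)
    out = np.empty(len(xq))
    for k, xv in enumerate(xq):
        i = int(np.clip(np.searchsorted(x, xv) - 1, 0, n - 2))
        t1, t2 = xv - x[i], x[i + 1] - xv
        out[k] = (
            M[i] * t2**3 / (6 * h[i])
            + M[i + 1] * t1**3 / (6 * h[i])
            + (y[i] / h[i] - M[i] * h[i] / 6) * t2
            + (y[i + 1] / h[i] - M[i + 1] * h[i] / 6) * t1
        )
    return out


def pca_first_component(X):
    """First-principal-component scores of the column-standardised matrix,
    via eigendecomposition of the correlation matrix; sign is oriented
    positively with the last column."""
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    corr = Z.T @ Z / (len(Z) - 1)
    w, v = np.linalg.eigh(corr)
    first = v[:, np.argmax(w)]
    scores = Z @ first
    if scores @ Z[:, -1] < 0:
        scores = -scores
    return scores
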