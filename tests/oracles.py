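"""Independent reference implementations used only to check the package.

These are deliberately naive (clarity over speed) and share no code with
the package's solvers.
"""

from __future__ import annotations

import numpy as np


def cd_oracle(
    X,
    y,
    weights,
    l1,
    l2=0.0,
    l1_per_feature=None,
    l2_per_feature=None,
    fit_intercept=True,
    tol=1e-14,
    max_iter=200_000,
):
    """Naive cyclic coordinate descent on the raw-scale weighted objective.

    Minimizes 1/2 sum_i w_i (y_i - b0 - x_i . b)^2
              + sum_j l1_j |b_j| + sum_j l2_j b_j^2.

    Per-feature penalties allow emulating internal standardization: a fit
    with predictors standardized to weighted sd s_j and a common (l1, l2)
    equals a raw-scale fit with l1_j = l1 * s_j and l2_j = l2 * s_j**2.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    n, p = X.shape
    l1v = np.full(p, l1) if l1_per_feature is None else np.asarray(l1_per_feature, float)
    l2v = np.full(p, l2) if l2_per_feature is None else np.asarray(l2_per_feature, float)
    beta = np.zeros(p)
    b0 = 0.0
    for _ in range(max_iter):
        max_delta = 0.0
        if fit_intercept:
            resid = y - X @ beta
            new_b0 = float(w @ resid) / float(w.sum())
            max_delta = max(max_delta, abs(new_b0 - b0))
            b0 = new_b0
        for j in range(p):
            partial = y - b0 - X @ beta + X[:, j] * beta[j]
            rho = float(w @ (X[:, j] * partial))
            z = float(w @ X[:, j] ** 2)
            if z == 0:
                continue
            num = np.sign(rho) * max(abs(rho) - l1v[j], 0.0)
            new = num / (z + 2.0 * l2v[j])
            max_delta = max(max_delta, abs(new - beta[j]))
            beta[j] = new
        if max_delta < tol:
            break
    return beta, b0


def weighted_sd(X, weights):
    """Weighted standard deviations (denominator sum w) about the weighted mean."""
    w = np.asarray(weights, float)
    mu = (w @ X) / w.sum()
    return np.sqrt((w @ (X - mu) ** 2) / w.sum())


def lasso_subgradient_gap(M, c, theta, l1):
    """Max violation of the optimality conditions of
    min theta^T M theta - 2 c^T theta + l1 ||theta||_1."""
    g = 2.0 * (M @ theta - c)
    gap = 0.0
    for j in range(len(theta)):
        if theta[j] != 0:
            gap = max(gap, abs(g[j] + l1 * np.sign(theta[j])))
        else:
            gap = max(gap, max(abs(g[j]) - l1, 0.0))
    return gap
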