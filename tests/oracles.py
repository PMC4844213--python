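"""Independent oracles used by the test suite.

Each function here is a from-first-principles implementation (brute-force
enumeration, the literal textbook formula, or a hand-rolled iterative
fitter) kept deliberately separate from the package code paths it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up by the literal definition.

    On sorted p-values, q(i) = min over j >= i of p(j) * m / j, capped at 1,
    mapped back to input order by a stable sort.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    q_sorted = np.empty(m)
    running_min = np.inf
    for i in range(m - 1, -1, -1):
        running_min = min(running_min, sorted_p[i] * m / (i + 1))
        q_sorted[i] = min(running_min, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def exact_rank_sum_p(x, y) -> float:
    """Two-sided exact rank-sum p by enumeration of all group assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (n1 + n2 + 1) / 2.0
    dev = abs(w_obs - mean_w)
    count = 0
    total = 0
    for idx in combinations(range(n1 + n2), n1):
        w = ranks[list(idx)].sum()
        if abs(w - mean_w) >= dev - 1e-9:
            count += 1
        total += 1
    return count / total


def newton_raphson_logistic(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-10, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood logistic regression by Newton-Raphson.

    ``X`` already includes the intercept column.  Returns (coefficients,
    standard errors).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * W[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1.0 - mu)
    cov = np.linalg.inv(X.T @ (X * W[:, None]))
    return beta, np.sqrt(np.diag(cov))


def chi2_statistic_formula(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared by the literal sum of (O - E)^2 / E."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    chi2 = float(((table - expected) ** 2 / expected).sum())
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    return chi2, float(stats.chi2.sf(chi2, dof))


def loocv_by_definition(fit_fn, predict_fn, values, labels) -> dict:
    """Held-out probabilities by literally excluding one sample at a time."""
    out = {}
    for sid in values.index:
        model = fit_fn(values.drop(index=sid), labels.drop(index=sid))
        out[sid] = predict_fn(model, values.loc[sid])
    return out
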