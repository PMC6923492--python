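"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own code paths: the design
matrix is assembled cell by cell with explicit loops, the least-squares
problem is solved through the normal equations with a pseudo-inverse,
the AUC is obtained by exhaustive pair counting, and the DeLong
placement values come from direct double loops.
"""

import numpy as np

FEATURES = ("mutation", "cnv", "exp_array", "exp_rnaseq")


def normal_equations_fit(crispr, shrna, features=None):
    """Solve the per-cell-line-intercept model by explicit normal equations.

    Returns (beta, theta_dict, fitted_matrix, rss).
    """
    cv, sv = crispr.values, shrna.values
    M, N = cv.shape
    layers = []
    if features is not None:
        layers = [features.layer(name) for name in FEATURES]
    rows = []
    ys = []
    cells = []
    for i in range(M):
        for j in range(N):
            vals = [sv[i, j]] + [lay[i, j] for lay in layers]
            if np.isnan(cv[i, j]) or any(np.isnan(v) for v in vals):
                continue
            row = [0.0] * N + vals
            row[j] = 1.0
            rows.append(row)
            ys.append(cv[i, j])
            cells.append((i, j))
    X = np.array(rows)
    y = np.array(ys)
    coef = np.linalg.pinv(X.T @ X) @ (X.T @ y)
    fitted = np.full((M, N), np.nan)
    for row, (i, j) in zip(X, cells):
        fitted[i, j] = row @ coef
    rss = float(np.sum((y - X @ coef) ** 2))
    beta = coef[:N]
    names = ("shrna",) + FEATURES if features is not None else ("shrna",)
    theta = {name: coef[N + k] for k, name in enumerate(names)}
    return beta, theta, fitted, rss


def pair_counting_auc(pos, neg):
    """AUC by exhaustive enumeration of (positive, negative) pairs.

    Orientation: lower score = more essential = better for a positive.
    """
    wins = 0.0
    for p in pos:
        for n in neg:
            if p < n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def delong_components_bruteforce(pos, neg):
    """Placement values by direct enumeration (higher = positive class)."""
    m, n = len(pos), len(neg)
    v_pos = np.empty(m)
    for i, x in enumerate(pos):
        v_pos[i] = np.mean([1.0 if x > y else 0.5 if x == y else 0.0 for y in neg])
    v_neg = np.empty(n)
    for j, y in enumerate(neg):
        v_neg[j] = np.mean([1.0 if x > y else 0.5 if x == y else 0.0 for x in pos])
    auc = v_pos.mean()
    var = np.var(v_pos, ddof=1) / m + np.var(v_neg, ddof=1) / n
    return auc, v_pos, v_neg, var
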