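"""Independent brute-force oracles, coded with plain loops so that they
share nothing with the vectorized implementations they check."""

from __future__ import annotations

from itertools import permutations

import numpy as np


def stability_oracle(x: np.ndarray) -> dict[str, np.ndarray]:
    """All nine stability indices by direct, spreadsheet-style summation."""
    x = np.asarray(x, float)
    G, E = x.shape
    row_mean = [sum(x[i, j] for j in range(E)) / E for i in range(G)]
    col_mean = [sum(x[i, j] for i in range(G)) / G for j in range(E)]
    grand = sum(row_mean) / G
    e = [col_mean[j] - grand for j in range(E)]
    see = sum(ej ** 2 for ej in e)

    S2 = np.array([
        sum((x[i, j] - row_mean[i]) ** 2 for j in range(E)) / (E - 1)
        for i in range(G)
    ])
    b = np.array([
        sum((x[i, j] - row_mean[i]) * e[j] for j in range(E)) / see
        for i in range(G)
    ])
    s2d = np.array([
        sum((x[i, j] - row_mean[i] - b[i] * e[j]) ** 2 for j in range(E))
        / (E - 2)
        for i in range(G)
    ]) if E > 2 else np.full(G, np.nan)
    r2 = np.array([
        b[i] ** 2 * see
        / sum((x[i, j] - row_mean[i]) ** 2 for j in range(E))
        for i in range(G)
    ])
    W = np.array([
        sum((x[i, j] - row_mean[i] - col_mean[j] + grand) ** 2
            for j in range(E))
        for i in range(G)
    ])
    Wsum = sum(W)
    sigma2 = np.array([
        (G * (G - 1) * W[i] - Wsum) / ((G - 1) * (G - 2) * (E - 1))
        for i in range(G)
    ]) if G > 2 else np.full(G, np.nan)
    b_min = min(b)
    D2 = np.array([
        sum((x[i, j] - row_mean[i] - b_min * e[j]) ** 2 for j in range(E))
        for i in range(G)
    ])
    P = np.array([
        sum((x[i, j] - max(x[k, j] for k in range(G))) ** 2 for j in range(E))
        / (2 * E)
        for i in range(G)
    ])
    # corrected-rank variance: rank x_ij - x_i. + x.. within each environment
    corrected = [[x[i, j] - row_mean[i] + grand for j in range(E)]
                 for i in range(G)]
    ranks = np.zeros((G, E))
    for j in range(E):
        colvals = [corrected[i][j] for i in range(G)]
        for i in range(G):
            less = sum(1 for v in colvals if v < colvals[i])
            equal = sum(1 for v in colvals if v == colvals[i])
            ranks[i, j] = less + (equal + 1) / 2.0
    S4 = np.array([
        sum((ranks[i, j] - sum(ranks[i]) / E) ** 2 for j in range(E)) / (E - 1)
        for i in range(G)
    ])
    return {"b_i": b, "s2_di": s2d, "r2_i": r2, "W_i": W, "sigma2_i": sigma2,
            "D2_i": D2, "P_i": P, "S2_xi": S2, "S4_i": S4}


def _r2_ols(y: np.ndarray, X: np.ndarray) -> float:
    n = y.size
    Xc = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    coef, _, _, _ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ coef
    tss = ((y - y.mean()) ** 2).sum()
    return 1.0 - (resid ** 2).sum() / tss


def lmg_permutation_oracle(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """LMG shares as the plain average over all p! orderings of the
    sequential R^2 gain of each regressor."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    p = X.shape[1]
    shares = np.zeros(p)
    orders = list(permutations(range(p)))
    for order in orders:
        r2_prev = 0.0
        included: list[int] = []
        for k in order:
            included.append(k)
            r2_now = _r2_ols(y, X[:, included])
            shares[k] += r2_now - r2_prev
            r2_prev = r2_now
    return shares / len(orders)
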