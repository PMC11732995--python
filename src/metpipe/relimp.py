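"""LMG relative importance: decomposing regression R^2 among regressors.

The LMG share of regressor k is its expected sequential R^2 gain when the
regressors enter the model in a uniformly random order, computed here by
the equivalent subset-weighted sum

    share_k = sum over S subset of P\\{k} of
              |S|! (p - |S| - 1)! / p! * (R^2(S + {k}) - R^2(S)),

with every R^2 from an OLS fit with intercept.  Shares are nonnegative and
sum exactly to the full-model R^2.  Enumeration is exhaustive (2^p fits),
intended for p <= 10.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

__all__ = ["LmgResult", "lmg", "stacked_importance"]


class LmgResult:
    """Shares per regressor plus the full-model R^2."""

    def __init__(self, shares: dict[str, float], r2_full: float):
        self.shares = shares
        self.r2_full = r2_full
        self.method = "lmg"

    def normalized(self) -> dict[str, float]:
        """Shares rescaled to sum to 1 (fraction of explained variance)."""
        if self.r2_full == 0:
            return {k: 0.0 for k in self.shares}
        return {k: v / self.r2_full for k, v in self.shares.items()}

    def __repr__(self) -> str:  # pragma: no cover
        inner = ", ".join(f"{k}={v:.4f}" for k, v in self.shares.items())
        return f"LmgResult(r2_full={self.r2_full:.4f}, {inner})"


def _subset_r2(y: np.ndarray, X: np.ndarray, tss: float) -> dict[frozenset, float]:
    """R^2 of every regressor subset, via least squares on centered data."""
    n, p = X.shape
    r2: dict[frozenset, float] = {frozenset(): 0.0}
    for size in range(1, p + 1):
        for S in combinations(range(p), size):
            Xs = X[:, S]
            coef, _, _, _ = np.linalg.lstsq(Xs, y, rcond=None)
            rss = float(((y - Xs @ coef) ** 2).sum())
            r2[frozenset(S)] = 1.0 - rss / tss
    return r2


def lmg(y, X: pd.DataFrame) -> LmgResult:
    """LMG decomposition of R^2 for an OLS-with-intercept regression.

    ``X`` is a regressor table (columns = regressors).  Constant columns
    are rejected; collinear columns raise with their names.
    """
    X = pd.DataFrame(X)
    names = list(X.columns)
    p = len(names)
    y = np.asarray(y, float)
    n = y.size
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")
    Xv = X.to_numpy(float)

    constant = [nm for nm, col in zip(names, Xv.T) if np.ptp(col) == 0]
    if constant:
        raise ValueError(f"constant regressor column(s): {constant}")
    if np.linalg.matrix_rank(Xv - Xv.mean(axis=0)) < p:
        # name the smallest collinear set by checking each column against rest
        collinear = []
        for i in range(p):
            rest = np.delete(Xv, i, axis=1)
            _, res, _, _ = np.linalg.lstsq(
                np.column_stack([rest, np.ones(n)]), Xv[:, i], rcond=None
            )
            if res.size == 0 or res[0] < 1e-10 * n:
                collinear.append(names[i])
        raise ValueError(f"rank-deficient regressor matrix; collinear: {collinear}")

    # centering makes the intercept implicit in every subset fit
    yc = y - y.mean()
    Xc = Xv - Xv.mean(axis=0)
    tss = float(yc @ yc)
    if tss == 0:
        raise ValueError("response has zero variance")

    r2 = _subset_r2(yc, Xc, tss)
    shares = {}
    pf = factorial(p)
    for k in range(p):
        others = [i for i in range(p) if i != k]
        total = 0.0
        for size in range(0, p):
            w = factorial(size) * factorial(p - size - 1) / pf
            for S in combinations(others, size):
                fs = frozenset(S)
                total += w * (r2[fs | {k}] - r2[fs])
        shares[names[k]] = total
    return LmgResult(shares=shares, r2_full=r2[frozenset(range(p))])


def stacked_importance(models: list[tuple[str, LmgResult]]) -> pd.DataFrame:
    """Long table for stacked-bar reporting of several LMG decompositions.

    One row per (model label, regressor): share on the R^2 scale, the
    share normalized to the model's R^2, and the model's full R^2.
    """
    rows = []
    for label, res in models:
        norm = res.normalized()
        for reg, share in res.shares.items():
            rows.append({
                "label": label,
                "regressor": reg,
                "share": share,
                "share_normalized": norm[reg],
                "r2_full": res.r2_full,
            })
    return pd.DataFrame(
        rows, columns=["label", "regressor", "share",
                       "share_normalized", "r2_full"]
    )
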