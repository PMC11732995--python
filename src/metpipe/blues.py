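"""Best linear unbiased estimates (BLUEs) of cultivar means per growing
condition.

Model, fitted separately for every (trait, growing condition):

    y_irc = mu + g_i + R_r + C_c + e,
    R_r ~ N(0, var_row),  C_c ~ N(0, var_col),  e ~ N(0, var_resid),

with cultivar effects g_i fixed and the row/column effects of the field grid
random, absorbing uneven soil-fertility gradients.  The cultivar BLUE is the
estimated marginal mean mu + g_i.

Estimation is residual maximum likelihood (REML) on the two variance ratios
(var_row/var_resid, var_col/var_resid), profiled over the fixed effects and
the residual variance.  Because the random structure has only
n_rows + n_cols levels, the Woodbury identity reduces every likelihood
evaluation to small dense solves, which keeps a 220-cultivar condition in
the low milliseconds.  When the layout is unusable (row/column missing for
most plots, a degenerate grid, or a failed fit) the estimator falls back to
per-cultivar arithmetic means and flags it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

__all__ = ["BlueModelFit", "fit_blues", "build_blue_table", "blue_matrix"]

_CONDITION_KEY = ["year", "location", "management"]


@dataclass
class BlueModelFit:
    """Result of one per-condition fit."""

    blues: pd.Series  # genotype -> mu + g_i
    mu: float
    var_row: float
    var_col: float
    var_resid: float
    n_obs: int
    converged: bool
    fallback: str = "none"  # "none" | "means"

    @property
    def g(self) -> pd.Series:
        """Genotype effects under sum-to-zero coding."""
        return self.blues - self.mu


def _reml_two_vc(y: np.ndarray, gidx: np.ndarray, n_g: int,
                 ridx: np.ndarray, n_r: int,
                 cidx: np.ndarray, n_c: int,
                 tol: float = 1e-8, maxiter: int = 200):
    """Profiled REML for y = X beta + Zr ur + Zc uc + e.

    X is the genotype one-hot matrix (no intercept), so beta_i = mu + g_i
    directly.  Returns (beta, lam_r, lam_c, sigma2_e, converged).
    """
    n = y.size
    p = n_g
    # sufficient statistics (computed once)
    X = np.zeros((n, p))
    X[np.arange(n), gidx] = 1.0
    Zr = np.zeros((n, n_r))
    Zr[np.arange(n), ridx] = 1.0
    Zc = np.zeros((n, n_c))
    Zc[np.arange(n), cidx] = 1.0
    Z = np.hstack([Zr, Zc])
    q = n_r + n_c

    XtX = X.T @ X
    XtZ = X.T @ Z
    Xty = X.T @ y
    ZtZ = Z.T @ Z
    Zty = Z.T @ y
    yty = float(y @ y)

    def neg2reml(theta: np.ndarray):
        lam = np.empty(q)
        lam[:n_r] = np.exp(theta[0])
        lam[n_r:] = np.exp(theta[1])
        s = np.sqrt(lam)
        # M = I_q + Lam^1/2 Z'Z Lam^1/2
        M = np.eye(q) + (ZtZ * s).T * s  # s[i]*ZtZ[i,j]*s[j]
        try:
            Lm = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        logdetH = 2.0 * np.log(np.diag(Lm)).sum()
        # A = M^{-1} Lam^1/2 Z'x for x in {X cols, y}
        B = np.linalg.solve(M, (XtZ * s).T)  # q x p
        by = np.linalg.solve(M, Zty * s)  # q
        S = XtX - (XtZ * s) @ B  # X' H^-1 X
        v = Xty - (XtZ * s) @ by  # X' H^-1 y
        try:
            Ls = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        beta = np.linalg.solve(Ls.T, np.linalg.solve(Ls, v))
        logdetS = 2.0 * np.log(np.diag(Ls)).sum()
        # r' H^-1 r = y'H^-1 y - beta' X'H^-1 y
        yHy = yty - float((Zty * s) @ by)
        rHr = yHy - float(beta @ v)
        rHr = max(rHr, 1e-300)
        sigma2 = rHr / (n - p)
        val = (n - p) * np.log(sigma2) + logdetH + logdetS
        return val, beta, sigma2

    def objective(theta):
        return neg2reml(theta)[0]

    res = minimize(
        objective, x0=np.array([-2.0, -2.0]), method="Nelder-Mead",
        options={"xatol": tol ** 0.5, "fatol": tol, "maxiter": maxiter * 10},
    )
    # the REML optimum may sit on the boundary (a zero variance component);
    # compare against the boundary candidates and keep the best
    floor = -34.0  # exp(-34) ~ 2e-15: numerically a zero component
    candidates = [
        res.x,
        np.array([floor, res.x[1]]),
        np.array([res.x[0], floor]),
        np.array([floor, floor]),
    ]
    vals = [neg2reml(c) for c in candidates]
    best = min(range(len(candidates)), key=lambda i: vals[i][0])
    val, beta, sigma2 = vals[best]
    theta = candidates[best]
    if not np.isfinite(val) or beta is None:
        return None

    def _lam(t: float) -> float:
        return 0.0 if t <= floor else float(np.exp(t))

    return beta, _lam(theta[0]), _lam(theta[1]), float(sigma2), bool(res.success)


def _means_fit(sub: pd.DataFrame, reason: str) -> BlueModelFit:
    means = sub.groupby("genotype", observed=True)["value"].mean().sort_index()
    logger.debug("BLUE fallback to means (%s)", reason)
    vr = float(sub.groupby("genotype")["value"].var().mean())
    return BlueModelFit(
        blues=means, mu=float(means.mean()),
        var_row=0.0, var_col=0.0,
        var_resid=vr if np.isfinite(vr) else 0.0,
        n_obs=int(len(sub)), converged=True, fallback="means",
    )


def fit_blues(
    records: pd.DataFrame,
    trait: str,
    condition: dict | tuple | None = None,
    max_missing_layout: float = 0.5,
) -> BlueModelFit:
    """Fit the row-column model for one trait within one growing condition.

    ``condition`` may be a ``(year, location, management)`` tuple, a dict of
    those keys, or None when ``records`` is already restricted.  Falls back
    to arithmetic genotype means when the layout is missing for more than
    ``max_missing_layout`` of the plots, when the grid is degenerate, or
    when REML fails.
    """
    sub = records[(records["trait"] == trait)]
    if condition is not None:
        if isinstance(condition, tuple):
            condition = dict(zip(_CONDITION_KEY, condition))
        for k, v in condition.items():
            sub = sub[sub[k] == v]
    sub = sub[sub["value"].notna()]
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r} in condition")
    if sub["genotype"].nunique() < 2:
        raise ValueError("need >= 2 genotypes with observations")

    layout_ok = sub[["row", "col"]].notna().all(axis=1)
    if layout_ok.mean() < (1.0 - max_missing_layout):
        return _means_fit(sub, "layout missing")
    sub = sub[layout_ok]

    g_codes, g_levels = pd.factorize(sub["genotype"], sort=True)
    r_codes, r_levels = pd.factorize(sub["row"], sort=True)
    c_codes, c_levels = pd.factorize(sub["col"], sort=True)
    n = len(sub)
    if len(r_levels) < 2 or len(c_levels) < 2 or n <= len(g_levels):
        return _means_fit(sub, "degenerate layout")

    y = sub["value"].to_numpy(float)
    out = _reml_two_vc(y, g_codes, len(g_levels),
                       r_codes, len(r_levels), c_codes, len(c_levels))
    if out is None:
        return _means_fit(sub, "REML failure")
    beta, lam_r, lam_c, sigma2, converged = out
    blues = pd.Series(beta, index=pd.Index(g_levels, name="genotype"))
    return BlueModelFit(
        blues=blues, mu=float(blues.mean()),
        var_row=lam_r * sigma2, var_col=lam_c * sigma2, var_resid=sigma2,
        n_obs=n, converged=converged, fallback="none",
    )


def build_blue_table(
    records: pd.DataFrame,
    traits: list[str] | None = None,
    conditions: list[tuple] | None = None,
) -> pd.DataFrame:
    """Apply :func:`fit_blues` per (trait, condition); long result table.

    Returns columns: genotype, year, location, management, trait, blue,
    fallback.  Cells with no data are skipped.
    """
    if traits is None:
        traits = sorted(records["trait"].unique())
    if conditions is None:
        conditions = sorted(
            records[_CONDITION_KEY].drop_duplicates().itertuples(index=False)
        )
    rows = []
    for trait in traits:
        tsub = records[(records["trait"] == trait) & records["value"].notna()]
        if tsub.empty:
            continue
        grouped = dict(tuple(tsub.groupby(_CONDITION_KEY, observed=True)))
        for cond in conditions:
            cond = tuple(cond)
            sub = grouped.get(cond)
            if sub is None or sub["genotype"].nunique() < 2:
                continue
            fit = fit_blues(sub, trait, condition=None)
            year, location, management = cond
            df = fit.blues.rename("blue").reset_index()
            df["year"] = year
            df["location"] = location
            df["management"] = management
            df["trait"] = trait
            df["fallback"] = fit.fallback
            rows.append(df)
    if not rows:
        return pd.DataFrame(
            columns=["genotype", "year", "location", "management",
                     "trait", "blue", "fallback"]
        )
    out = pd.concat(rows, ignore_index=True)
    return out[["genotype", "year", "location", "management",
                "trait", "blue", "fallback"]]


def blue_matrix(blue_table: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Pivot one trait to a genotype x condition-key matrix (may hold NaN)."""
    sub = blue_table[blue_table["trait"] == trait].copy()
    sub["condition"] = (
        sub["year"].astype(str) + "/" + sub["location"] + "/" + sub["management"]
    )
    return sub.pivot_table(index="genotype", columns="condition",
                           values="blue", aggfunc="first")
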