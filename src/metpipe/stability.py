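"""Nine yield-stability indices on a genotype x environment BLUE matrix,
and the regression of yield stability on component-trait stability.

With x_ij the BLUE of genotype i in environment j (a growing condition),
row means x_i., column means x_.j, grand mean x.., and environment index
e_j = x_.j - x.., the indices are:

================  ===========================================================
S2_xi             environmental variance (Roemer): var over environments
b_i               regression coefficient on the environmental index
                  (Finlay-Wilkinson)
s2_di             deviation mean squares from that regression
                  (Eberhart-Russell, without an error-variance correction:
                  the inputs are BLUEs, not plot replicates)
r2_i              coefficient of determination of the same regression
                  (Pinthus)
W_i               ecovalence: the genotype's share of the interaction sum of
                  squares (Wricke)
sigma2_i          stability variance (Shukla), a rescaling of W_i
D2_i              genotypic stability (Hanson): deviations from the line
                  with the smallest slope b_min among all genotypes
P_i               genotypic superiority (Lin-Binns): mean squared distance
                  from the best genotype in each environment
S4_i              variance of corrected ranks (Nassar-Huehn): ranks of
                  x_ij - x_i. + x.. within environments
================  ===========================================================

Smaller values mean more stable for every index except b_i (static
stability when b_i ~ 0, agronomic stability near 1) and r2_i (dynamic
stability when near 1); that orientation is exposed in
:data:`INDEX_DIRECTION`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .blues import blue_matrix
from .progress import significance_stars

logger = logging.getLogger(__name__)

__all__ = [
    "INDEX_NAMES",
    "INDEX_DIRECTION",
    "build_trait_matrix",
    "stability_indices",
    "tfi_regressor",
    "si_regression",
]

INDEX_NAMES = ("b_i", "s2_di", "r2_i", "W_i", "sigma2_i",
               "D2_i", "P_i", "S2_xi", "S4_i")

#: How each index orders genotypes: "smaller" = small values are stable,
#: "larger" = values near the maximum (1) are stable, "near_one" = values
#: close to 1 indicate average responsiveness.
INDEX_DIRECTION = {
    "S2_xi": "smaller",
    "b_i": "near_one",
    "s2_di": "smaller",
    "r2_i": "larger",
    "W_i": "smaller",
    "sigma2_i": "smaller",
    "D2_i": "smaller",
    "P_i": "smaller",
    "S4_i": "smaller",
}


def build_trait_matrix(
    blue_table: pd.DataFrame,
    trait: str,
    conditions: list[str] | None = None,
) -> pd.DataFrame:
    """Complete-case genotype x environment matrix of BLUEs for one trait.

    Genotypes with any missing cell across the selected conditions are
    dropped (logged).  Errors when fewer than 3 genotypes or 3 environments
    survive.  Rows are ordered by genotype id.
    """
    mat = blue_matrix(blue_table, trait)
    if conditions is not None:
        cols = [c for c in conditions if c in mat.columns]
        mat = mat[cols]
    if mat.shape[1] < 3:
        raise ValueError(f"trait {trait!r} present in < 3 conditions")
    before = len(mat)
    mat = mat.dropna(axis=0)
    dropped = before - len(mat)
    if dropped:
        logger.info("build_trait_matrix(%s): dropped %d incomplete genotype(s)",
                    trait, dropped)
    if len(mat) < 3:
        raise ValueError("fewer than 3 complete-case genotypes survive")
    return mat.sort_index()


def stability_indices(mat: pd.DataFrame) -> pd.DataFrame:
    """All nine stability indices for every genotype of one trait matrix.

    Exact identities (asserted in the test suite): sum_i W_i equals the
    interaction sum of squares, mean_i b_i = 1, and mean_i sigma2_i equals
    the interaction mean square.
    """
    x = mat.to_numpy(float)
    G, E = x.shape
    if G < 2 or E < 2:
        raise ValueError("need at least 2 genotypes and 2 environments")
    row_m = x.mean(axis=1, keepdims=True)  # x_i.
    col_m = x.mean(axis=0, keepdims=True)  # x_.j
    grand = x.mean()
    e = (col_m - grand).ravel()  # environmental index e_j
    dev = x - row_m  # x_ij - x_i.
    see = float(e @ e)

    S2_xi = (dev ** 2).sum(axis=1) / (E - 1)
    if see > 0:
        b = (dev @ e) / see
    else:
        b = np.ones(G)
    resid = dev - np.outer(b, e)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2_di = (resid ** 2).sum(axis=1) / (E - 2) if E > 2 else np.full(G, np.nan)
        denom = (dev ** 2).sum(axis=1)
        r2 = np.where(denom > 0, b ** 2 * see / denom, np.nan)

    inter = x - row_m - col_m + grand
    W = (inter ** 2).sum(axis=1)
    Wsum = W.sum()
    if G > 2:
        sigma2 = (G * (G - 1) * W - Wsum) / ((G - 1) * (G - 2) * (E - 1))
    else:
        sigma2 = np.full(G, np.nan)

    b_min = b.min()
    D2 = ((dev - np.outer(np.full(G, b_min), e)) ** 2).sum(axis=1)

    M_j = x.max(axis=0)
    P = ((x - M_j) ** 2).sum(axis=1) / (2 * E)

    corrected = x - row_m + grand
    ranks = np.apply_along_axis(rankdata, 0, corrected)
    S4 = ((ranks - ranks.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) / (E - 1)

    out = pd.DataFrame(
        {
            "b_i": b, "s2_di": s2_di, "r2_i": r2, "W_i": W,
            "sigma2_i": sigma2, "D2_i": D2, "P_i": P,
            "S2_xi": S2_xi, "S4_i": S4,
        },
        index=mat.index,
    )
    out.attrs["n_environments"] = E
    out.attrs["n_genotypes"] = G
    return out


def tfi_regressor(
    blue_table: pd.DataFrame,
    genotypes: list[str],
    conditions: list[str] | None = None,
    mode: str = "mean_tfi",
    si_name: str = "W_i",
) -> pd.Series:
    """Per-genotype total-fungal-infection regressor for the stability model.

    mode="mean_tfi" (default): the genotype's mean TFI BLUE over the
    condition subset.  mode="si_of_tfi": the chosen stability index applied
    to the TFI matrix itself.
    """
    if mode not in ("mean_tfi", "si_of_tfi"):
        raise ValueError("mode must be 'mean_tfi' or 'si_of_tfi'")
    sub = blue_table[blue_table["trait"] == "TFI"]
    if sub.empty:
        raise ValueError("no TFI entries in the BLUE table; run QC first")
    mat = blue_matrix(blue_table, "TFI")
    if conditions is not None:
        mat = mat[[c for c in conditions if c in mat.columns]]
    if mode == "mean_tfi":
        vec = mat.mean(axis=1)
    else:
        vec = stability_indices(mat.dropna(axis=0))[si_name]
    vec = vec.reindex(genotypes)
    return vec.rename("TFI")


def si_regression(
    si_tables: dict[str, pd.DataFrame],
    si_name: str,
    response: str = "Seedyield",
    regressors: list[str] | None = None,
    tfi: pd.Series | None = None,
) -> pd.DataFrame:
    """OLS of yield stability on component-trait stability, per index.

    ``si_tables`` maps trait name -> stability table (genotype-indexed);
    ``tfi`` is the optional per-genotype infection regressor.  Observations
    are the genotypes common to every input.  Constant columns are dropped
    with a warning.  Returns a long table (term, beta, p_value, stars,
    r2_full, n) tagged with the index name.
    """
    if regressors is None:
        regressors = [t for t in si_tables if t != response]
    cols = {t: si_tables[t][si_name] for t in [response] + list(regressors)}
    data = pd.DataFrame({f"SI_{t}": v for t, v in cols.items()})
    if tfi is not None:
        data["TFI"] = tfi
    data = data.dropna()
    yname = f"SI_{response}"
    xnames = [c for c in data.columns if c != yname]
    if len(data) < len(xnames) + 2:
        raise ValueError("too few common genotypes for the regression")

    X = data[xnames]
    keep = [c for c in X.columns if X[c].nunique() > 1]
    droppedc = set(xnames) - set(keep)
    if droppedc:
        logger.warning("si_regression(%s): constant regressor(s) dropped: %s",
                       si_name, sorted(droppedc))
    Xc = sm.add_constant(X[keep])
    fit = sm.OLS(data[yname], Xc).fit()
    rows = []
    for term in Xc.columns:
        rows.append({
            "si": si_name,
            "term": "Intercept" if term == "const" else term,
            "beta": float(fit.params[term]),
            "p_value": float(fit.pvalues[term]),
            "stars": significance_stars(float(fit.pvalues[term])),
            "r2_full": float(fit.rsquared),
            "n": len(data),
        })
    return pd.DataFrame(rows)
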