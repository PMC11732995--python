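"""Breeding progress: trait gain per year of cultivar release.

Breeding progress (BP) of a trait within one growing condition is the slope
of the ordinary least squares regression of cultivar BLUEs on cultivar year
of release.  A second-stage multiple regression across growing conditions
then decomposes BP of grain yield into the BP of component traits
(thousand-grain weight, harvest index, straw mass, grains per spike, spike
number), optionally within levels of a single grouping factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["BpEstimate", "estimate_bp", "bp_table", "bp_regression",
            "significance_stars"]

_CONDITION_KEY = ["year", "location", "management"]


@dataclass(frozen=True)
class BpEstimate:
    trait: str
    condition: str  # "year/location/management"
    bp: float  # trait units per release year
    p_value: float
    r2: float
    n: int


def significance_stars(p: float) -> str:
    """Conventional significance stars: * 5%, ** 1%, *** 0.1%."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def estimate_bp(
    blue_table: pd.DataFrame,
    meta: pd.DataFrame,
    trait: str,
    condition: tuple,
    panel: list[str] | None = None,
) -> BpEstimate:
    """OLS slope of BLUE on release year for one trait x condition.

    ``meta`` maps genotype -> release_year; ``panel`` optionally restricts
    to a cultivar subset (e.g. the breeding-history panel).
    """
    year, location, management = condition
    sub = blue_table[
        (blue_table["trait"] == trait)
        & (blue_table["year"] == year)
        & (blue_table["location"] == location)
        & (blue_table["management"] == management)
    ]
    if panel is not None:
        sub = sub[sub["genotype"].isin(set(panel))]
    merged = sub.merge(meta[["genotype", "release_year"]], on="genotype")
    merged = merged[merged["blue"].notna() & merged["release_year"].notna()]
    if len(merged) < 3:
        raise ValueError("need >= 3 cultivars with BLUE and release year")
    x = merged["release_year"].to_numpy(float)
    y = merged["blue"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("all release years equal: slope undefined")
    res = stats.linregress(x, y)
    return BpEstimate(
        trait=trait,
        condition=f"{year}/{location}/{management}",
        bp=float(res.slope),
        p_value=float(res.pvalue),
        r2=float(res.rvalue ** 2),
        n=len(merged),
    )


def bp_table(
    blue_table: pd.DataFrame,
    meta: pd.DataFrame,
    traits: list[str],
    panel: list[str] | None = None,
) -> pd.DataFrame:
    """BP for every trait x growing condition present in the BLUE table."""
    rows = []
    conds = (
        blue_table[_CONDITION_KEY].drop_duplicates().itertuples(index=False)
    )
    for cond in conds:
        cond = tuple(cond)
        for trait in traits:
            try:
                est = estimate_bp(blue_table, meta, trait, cond, panel=panel)
            except ValueError:
                continue
            rows.append(est.__dict__)
    out = pd.DataFrame(rows)
    if not out.empty:
        out["stars"] = out["p_value"].map(significance_stars)
    return out


def bp_regression(
    bp_tbl: pd.DataFrame,
    response: str = "Seedyield",
    regressors: list[str] | None = None,
    grouping: str | None = None,
) -> pd.DataFrame:
    """Second-stage OLS of BP_response on BP of component traits.

    Observations are growing conditions (one BP vector each), unweighted.
    ``grouping`` is None (single pooled "all" model) or one of "year",
    "location", "management" -- then one model per level *plus* the pooled
    model.  Constant regressor columns are dropped with a warning; levels
    with fewer observations than regressors + 2 are skipped.

    Returns a long table: level, term, beta, p_value, stars, r2_full, n.
    """
    if regressors is None:
        regressors = ["TGW", "Harvest_Index_bio", "Straw",
                      "Grain_per_spike_bio", "Spike_number_bio"]
    wide = bp_tbl.pivot_table(index="condition", columns="trait",
                              values="bp", aggfunc="first")
    needed = [response] + regressors
    missing = [t for t in needed if t not in wide.columns]
    if missing:
        raise ValueError(f"BP table lacks trait(s): {missing}")
    wide = wide[needed].dropna()

    parts = wide.index.to_series().str.split("/", expand=True)
    parts.columns = _CONDITION_KEY

    levels: list[tuple[str, pd.DataFrame]] = [("all", wide)]
    if grouping is not None:
        if grouping not in _CONDITION_KEY:
            raise ValueError(f"unknown grouping factor {grouping!r}")
        for lv, idx in parts.groupby(grouping).groups.items():
            levels.append((str(lv), wide.loc[idx]))

    rows = []
    for label, data in levels:
        n = len(data)
        if n < len(regressors) + 2:
            logger.warning("bp_regression skipped level %s (n=%d too small)",
                           label, n)
            continue
        X = data[regressors]
        keep = [c for c in X.columns if X[c].nunique() > 1]
        droppedc = set(X.columns) - set(keep)
        if droppedc:
            logger.warning("constant regressor(s) dropped in level %s: %s",
                           label, sorted(droppedc))
        Xc = sm.add_constant(X[keep])
        fit = sm.OLS(data[response], Xc).fit()
        for term in Xc.columns:
            rows.append({
                "level": label,
                "term": "Intercept" if term == "const" else term,
                "beta": float(fit.params[term]),
                "p_value": float(fit.pvalues[term]),
                "stars": significance_stars(float(fit.pvalues[term])),
                "r2_full": float(fit.rsquared),
                "n": n,
            })
    return pd.DataFrame(rows)
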