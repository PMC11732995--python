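"""Trait consistency between growing conditions via standardized major axis
(SMA) regression.

For each unordered pair of growing conditions, the BLUEs of the shared
cultivars in condition A are regressed on those in condition B with an SMA
line (errors in both variables; appropriate for a non-causal relation).
The coefficient of determination of that line, R^2_sma, equals the squared
Pearson correlation and measures how consistently the trait ranks cultivars
across the two conditions.

Pairs can be pooled or grouped by the factors the two conditions share
(year, location, management, or combinations); levels are compared with
one-way ANOVA followed by Fisher's least significant difference (LSD) test
rendered as a compact letter display.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .blues import blue_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "SmaResult",
    "sma_fit",
    "pairwise_consistency",
    "group_pairs",
    "anova_lsd",
    "summarize_groups",
]


@dataclass(frozen=True)
class SmaResult:
    slope: float
    intercept: float
    r2: float
    n: int


def sma_fit(x, y) -> SmaResult:
    """Standardized major axis line: slope = sign(r) * s_y/s_x.

    R^2 is the squared Pearson correlation (for the SMA line the coefficient
    of determination coincides with it).  Requires >= 3 complete pairs and
    non-degenerate variance on both axes.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("sma_fit needs >= 3 complete pairs")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance on one axis")
    r = float(np.corrcoef(x, y)[0, 1])
    sign = 1.0 if r >= 0 else -1.0
    slope = sign * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    return SmaResult(slope=float(slope), intercept=intercept, r2=r * r, n=n)


def pairwise_consistency(
    blue_table: pd.DataFrame,
    trait: str,
    conditions: list[str] | None = None,
    min_shared: int = 3,
) -> pd.DataFrame:
    """R^2_sma for every unordered pair of growing conditions sharing at
    least ``min_shared`` cultivars.

    Returns columns condition_a, condition_b (keys "year/loc/mgmt", a < b
    lexicographically), r2_sma, n.
    """
    mat = blue_matrix(blue_table, trait)
    if conditions is not None:
        mat = mat[[c for c in conditions if c in mat.columns]]
    cols = list(mat.columns)
    if len(cols) < 2:
        raise ValueError("trait present in fewer than 2 conditions")

    # pairwise-complete Pearson r and shared-n in one pass
    corr = mat.corr(min_periods=min_shared)
    notna = mat.notna().astype(int).to_numpy()
    shared = notna.T @ notna

    rows = []
    for i, j in itertools.combinations(range(len(cols)), 2):
        n = int(shared[i, j])
        r = corr.iat[i, j]
        if n < min_shared or not np.isfinite(r):
            continue
        a, b = sorted((cols[i], cols[j]))
        rows.append((a, b, float(r * r), n))
    out = pd.DataFrame(rows, columns=["condition_a", "condition_b",
                                      "r2_sma", "n"])
    out["trait"] = trait
    return out


def _split_key(key: str) -> dict[str, str]:
    year, location, management = key.split("/")
    return {"year": year, "location": location, "management": management}


def group_pairs(
    pairs: pd.DataFrame, fixed_factors: list[str] | None
) -> pd.DataFrame:
    """Assign each pair to a grouping level, keeping only pairs whose two
    conditions agree on every fixed factor.

    ``fixed_factors`` is a subset of {"year", "location", "management"};
    empty/None pools everything under level "all".  The level label is the
    "-"-join of the shared factor values.
    """
    out = pairs.copy()
    if not fixed_factors:
        out["level"] = "all"
        return out
    valid = {"year", "location", "management"}
    bad = set(fixed_factors) - valid
    if bad:
        raise ValueError(f"unknown grouping factor(s): {sorted(bad)}")

    fa = out["condition_a"].map(lambda k: _split_key(k))
    fb = out["condition_b"].map(lambda k: _split_key(k))
    keep = pd.Series(True, index=out.index)
    levels = []
    for a, b in zip(fa, fb):
        if all(a[f] == b[f] for f in fixed_factors):
            levels.append("-".join(a[f] for f in fixed_factors))
        else:
            levels.append(None)
    out["level"] = levels
    keep = out["level"].notna()
    return out[keep].reset_index(drop=True)


def anova_lsd(
    values_by_level: dict[str, np.ndarray], alpha: float = 0.05
) -> tuple[float, dict[str, str]]:
    """One-way ANOVA across levels, then unprotected Fisher LSD letters.

    Levels with fewer than two values are excluded (warned).  When the
    ANOVA is not significant at ``alpha`` every level shares letter "a";
    otherwise all pairwise t-tests use the pooled within-group mean square
    and its degrees of freedom, and a compact letter display is built by
    greedy insert-and-absorb over levels sorted by descending mean.
    """
    groups = {k: np.asarray(v, float) for k, v in values_by_level.items()}
    dropped = [k for k, v in groups.items() if v.size < 2]
    if dropped:
        logger.warning("anova_lsd excluded level(s) with < 2 values: %s", dropped)
    groups = {k: v for k, v in groups.items() if v.size >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 levels with >= 2 values each")

    names = list(groups)
    arrays = [groups[k] for k in names]
    anova_p = float(stats.f_oneway(*arrays).pvalue)

    if not np.isfinite(anova_p) or anova_p >= alpha:
        return anova_p, {k: "a" for k in names}

    N = sum(a.size for a in arrays)
    k = len(arrays)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / (N - k)
    df = N - k
    means = {nm: a.mean() for nm, a in zip(names, arrays)}
    ns = {nm: a.size for nm, a in zip(names, arrays)}

    def differ(a: str, b: str) -> bool:
        se = np.sqrt(mse * (1 / ns[a] + 1 / ns[b]))
        if se == 0:
            return means[a] != means[b]
        t = abs(means[a] - means[b]) / se
        p = 2 * stats.t.sf(t, df)
        return p < alpha

    order = sorted(names, key=lambda nm: (-means[nm], nm))
    letters = _compact_letters(order, differ)
    return anova_p, letters


def _compact_letters(order: list[str], differ) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``order``: levels sorted by descending mean.  ``differ(a, b)``: True if
    a and b are significantly different.  Levels sharing a letter are not
    significantly different.
    """
    # start from one all-inclusive group; for every significant pair split
    # each group containing both, then absorb redundant subsets
    groups: list[set[str]] = [set(order)]
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            if not differ(a, b):
                continue
            new_groups: list[set[str]] = []
            for grp in groups:
                if a in grp and b in grp:
                    new_groups.append(grp - {a})
                    new_groups.append(grp - {b})
                else:
                    new_groups.append(grp)
            groups = [g for g in new_groups
                      if g and not any(g < h for h in new_groups)]
    # deduplicate while keeping a stable order by best-ranked member
    seen: list[set[str]] = []
    for g in groups:
        if g not in seen:
            seen.append(g)
    groups = sorted(seen, key=lambda g: min(order.index(lv) for lv in g))
    # letter assignment in mean order
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, str] = {lv: "" for lv in order}
    for li, grp in enumerate(groups):
        for lv in order:
            if lv in grp:
                letters[lv] += alphabet[li % len(alphabet)]
    return letters


def summarize_groups(
    grouped_pairs: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-level max/mean/min of R^2_sma plus ANOVA p and LSD letters.

    Mirrors the reporting style of the consistency analysis: M (maximum),
    A (average), m (minimum) per level, with significance letters when at
    least two levels have two or more pairs.
    """
    agg = grouped_pairs.groupby("level")["r2_sma"].agg(
        n_pairs="size", max="max", mean="mean", min="min"
    )
    values = {lv: g["r2_sma"].to_numpy()
              for lv, g in grouped_pairs.groupby("level")}
    eligible = {k: v for k, v in values.items() if v.size >= 2}
    if len(eligible) >= 2:
        anova_p, letters = anova_lsd(values, alpha=alpha)
    else:
        anova_p, letters = np.nan, {}
    out = agg.reset_index()
    out["anova_p"] = anova_p
    out["letter"] = out["level"].map(letters).fillna("")
    return out
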