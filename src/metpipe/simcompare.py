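"""Comparing trait-trait correlation structure between field data and an
external crop-model output table.

Both inputs are genotype x trait tables.  For each trait pair the Pearson
correlation is computed in both tables; a pair is *concordant* when the
point (r_field, r_sim) lies close to the identity line (perpendicular
distance |r_field - r_sim| / sqrt(2) below ``d_max``) and both correlations
are substantial (|r| above ``r_min``).  The crop model itself is never run
here -- its outputs are just a table.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["corr_table", "compare"]


def corr_table(
    table: pd.DataFrame,
    traits: list[str] | None = None,
    min_n: int = 3,
) -> pd.DataFrame:
    """Half-matrix of pairwise-complete Pearson correlations.

    ``table``: genotype rows x trait columns.  Pairs with fewer than
    ``min_n`` complete observations or a constant trait are reported with
    missing r.  Returns columns trait_a, trait_b (sorted), r, n.
    """
    if traits is not None:
        table = table[[t for t in traits if t in table.columns]]
    cols = list(table.columns)
    rows = []
    for a, b in itertools.combinations(cols, 2):
        pair = table[[a, b]].dropna()
        n = len(pair)
        if n < min_n or pair[a].nunique() < 2 or pair[b].nunique() < 2:
            r = np.nan
        else:
            r = float(np.corrcoef(pair[a], pair[b])[0, 1])
        ta, tb = sorted((a, b))
        rows.append({"trait_a": ta, "trait_b": tb, "r": r, "n": n})
    return pd.DataFrame(rows)


def compare(
    field_corr: pd.DataFrame,
    sim_corr: pd.DataFrame,
    d_max: float = 0.09,
    r_min: float = 0.5,
) -> pd.DataFrame:
    """Join two correlation half-matrices and flag concordant pairs.

    concordant = (perpendicular distance to the 1:1 line < d_max)
                 and |r_field| > r_min and |r_sim| > r_min.

    The distance is geometric (|r_field - r_sim| / sqrt(2)); callers who
    prefer a vertical-difference threshold should pass
    ``d_max = delta / sqrt(2)``.
    """
    f = field_corr.rename(columns={"r": "r_field", "n": "n_field"})
    s = sim_corr.rename(columns={"r": "r_sim", "n": "n_sim"})
    merged = f.merge(s, on=["trait_a", "trait_b"], how="inner")
    n_only = len(f) + len(s) - 2 * len(merged)
    if merged.empty:
        raise ValueError("no shared trait pairs between field and simulation")
    if n_only:
        logger.info("compare: %d pair(s) present in only one table", n_only)
    merged["distance"] = (merged["r_field"] - merged["r_sim"]).abs() / math.sqrt(2)
    merged["concordant"] = (
        (merged["distance"] < d_max)
        & (merged["r_field"].abs() > r_min)
        & (merged["r_sim"].abs() > r_min)
    )
    merged.loc[merged[["r_field", "r_sim"]].isna().any(axis=1),
               "concordant"] = False
    return merged
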