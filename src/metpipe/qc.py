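"""Quality control of plot-level records.

Two cleaning steps are applied before any estimation:

* range recoding -- physically impossible values (negative measurements,
  grain yield above 3000 dt/ha, thousand-grain weight above 80 g) are
  recoded to missing, never deleted;
* the +/-4 standard deviation screen -- within each growing condition,
  observations of selected traits (harvest index and spike number by
  default) lying outside mean +/- k*sd over the condition's genotypes are
  excluded (dropped) as outliers.

The total fungal infection score (TFI) is the plain sum of the six visual
infection scores, assuming additivity of infected area.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import DISEASE_TRAITS, trait_registry

logger = logging.getLogger(__name__)

__all__ = [
    "RangeRule",
    "SdRule",
    "default_range_rules",
    "apply_range_rules",
    "apply_sd_rule",
    "compute_tfi",
]

_CONDITION_KEY = ["year", "location", "management"]


@dataclass(frozen=True)
class RangeRule:
    """Valid interval for one trait; values outside become missing."""

    trait: str
    min_valid: float = -math.inf
    max_valid: float = math.inf

    def __post_init__(self) -> None:
        if not self.min_valid < self.max_valid:
            raise ValueError("min_valid must be < max_valid")


@dataclass(frozen=True)
class SdRule:
    """Per-condition mean +/- k*sd outlier screen for selected traits."""

    traits: frozenset = frozenset({"Harvest_Index_bio", "Spike_number_bio"})
    k: float = 4.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")


def default_range_rules() -> list[RangeRule]:
    """Shipped defaults: yield <= 3000 dt/ha, TGW <= 80 g.  Nonnegativity of
    all registered nonnegative traits is enforced separately by
    :func:`apply_range_rules` regardless of explicit rules."""
    return [
        RangeRule("Seedyield", max_valid=3000.0),
        RangeRule("TGW", max_valid=80.0),
    ]


def apply_range_rules(
    records: pd.DataFrame,
    rules: list[RangeRule] | None = None,
    enforce_nonnegative: bool = True,
) -> tuple[pd.DataFrame, int]:
    """Recode out-of-range values to missing; never drop rows.

    Returns the cleaned copy and the number of values recoded.
    """
    if rules is None:
        rules = default_range_rules()
    registry = trait_registry()
    unknown = [r.trait for r in rules if r.trait not in registry]
    if unknown:
        raise ValueError(f"range rules reference unknown trait(s): {unknown}")

    out = records.copy()
    bad = pd.Series(False, index=out.index)
    for rule in rules:
        m = out["trait"] == rule.trait
        v = out["value"]
        bad |= m & v.notna() & ((v < rule.min_valid) | (v > rule.max_valid))
    if enforce_nonnegative:
        nonneg = {t for t, meta in registry.items() if meta.get("nonnegative")}
        m = out["trait"].isin(nonneg)
        bad |= m & out["value"].notna() & (out["value"] < 0)

    n_recoded = int(bad.sum())
    out.loc[bad, "value"] = np.nan
    return out, n_recoded


def apply_sd_rule(
    records: pd.DataFrame, rule: SdRule | None = None, min_group: int = 3
) -> tuple[pd.DataFrame, int]:
    """Drop per-condition outliers beyond mean +/- k*sd for ``rule.traits``.

    The mean and sample standard deviation (n-1 denominator) are computed per
    (growing condition, trait) over all non-missing observations.  Groups
    with fewer than ``min_group`` values are skipped.  Offending rows are
    removed; the number excluded is returned.
    """
    if rule is None:
        rule = SdRule()
    target = records["trait"].isin(rule.traits) & records["value"].notna()
    sub = records.loc[target]
    if sub.empty:
        return records.copy(), 0

    grp = sub.groupby(_CONDITION_KEY + ["trait"], observed=True)["value"]
    stats = grp.agg(["mean", "std", "count"])
    small = stats["count"] < min_group
    if small.any():
        logger.info("sd rule skipped %d group(s) with < %d values",
                    int(small.sum()), min_group)
    stats.loc[small, "std"] = np.nan  # skip: bounds become +/- inf below

    joined = sub.join(stats, on=_CONDITION_KEY + ["trait"])
    half = rule.k * joined["std"]
    outlier = (joined["value"] - joined["mean"]).abs() > half
    outlier &= half.notna()
    drop_idx = joined.index[outlier]
    out = records.drop(index=drop_idx).reset_index(drop=True)
    return out, int(len(drop_idx))


def compute_tfi(
    records: pd.DataFrame, policy: str = "strict"
) -> pd.DataFrame:
    """Append a per-plot ``TFI`` trait: the sum of the six infection scores.

    policy="strict" (default): TFI is missing when any of the six component
    scores is missing.  policy="available": sum the non-missing scores
    (missing only when all six are).
    """
    if policy not in ("strict", "available"):
        raise ValueError("policy must be 'strict' or 'available'")
    plot_key = ["genotype", "release_year", "year", "location", "management",
                "replicate", "row", "col"]
    dis = records[records["trait"].isin(DISEASE_TRAITS)]
    if dis.empty:
        raise ValueError("no disease-score records present; cannot build TFI")

    dis = dis.drop_duplicates(subset=plot_key + ["trait"])
    wide = dis.set_index(plot_key + ["trait"])["value"].unstack("trait")
    for t in DISEASE_TRAITS:
        if t not in wide.columns:
            wide[t] = np.nan
    wide = wide[list(DISEASE_TRAITS)]
    if policy == "strict":
        tfi = wide.sum(axis=1, min_count=len(DISEASE_TRAITS))
    else:
        tfi = wide.sum(axis=1, min_count=1)

    new = tfi.rename("value").reset_index()
    new["trait"] = "TFI"
    out = pd.concat(
        [records[records["trait"] != "TFI"], new[records.columns]],
        ignore_index=True,
    )
    return out
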