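"""CSV readers/writers for plot tables and cultivar metadata.

Plot data arrive as a wide per-plot CSV (one row per plot, one column per
trait) and are pivoted into the long canonical form of
:mod:`metpipe.schema`.  Arbitrary source headers are absorbed by a column
map (a plain dict or YAML file) translating them to canonical names; trait
columns are passed through unchanged so the map only needs entries for the
identifier columns.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .schema import (
    DISEASE_TRAITS,
    MANAGEMENT_LABELS,
    RECORD_COLUMNS,
    ManagementCode,
    trait_registry,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_plot_table",
    "write_plot_table",
    "validate_records",
    "read_cultivar_meta",
    "read_column_map",
]

#: Identifier columns that must be present (after column-map translation).
MANDATORY = ("genotype", "year", "location", "management")
#: Optional identifier columns, filled with defaults when absent.
OPTIONAL = ("release_year", "replicate", "row", "col")

_ID_COLUMNS = MANDATORY + OPTIONAL

DEFAULT_NA = ("NA", "")


def read_column_map(path: str | Path) -> dict:
    """Load a YAML column map ``{source_header: canonical_name}``."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    if not isinstance(mapping, Mapping):
        raise ValueError("column map must be a mapping of source -> canonical names")
    return dict(mapping)


def read_plot_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    na_tokens: tuple[str, ...] = DEFAULT_NA,
    trait_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Read a wide per-plot CSV into the long canonical record table.

    Parameters
    ----------
    path
        CSV file with a header row; one row per plot.
    column_map
        Optional translation of source headers to canonical names
        (``genotype``, ``year``, ``location``, ``management``,
        ``release_year``, ``replicate``, ``row``, ``col`` and trait names).
    na_tokens
        Strings interpreted as missing.
    trait_columns
        Columns to treat as traits.  Default: every non-identifier column.

    Returns
    -------
    DataFrame in long form, one row per (plot, trait), including rows whose
    value is missing (missingness is information, not absence).
    """
    wide = pd.read_csv(
        path, na_values=list(na_tokens), keep_default_na=False, dtype=str
    )
    if column_map:
        wide = wide.rename(columns=dict(column_map))

    missing = [c for c in MANDATORY if c not in wide.columns]
    if missing:
        raise ValueError(
            f"plot table is missing mandatory column(s): {', '.join(missing)}"
        )

    for col, default in (("replicate", 1), ("release_year", np.nan),
                         ("row", np.nan), ("col", np.nan)):
        if col not in wide.columns:
            wide[col] = default

    if trait_columns is None:
        trait_columns = [c for c in wide.columns if c not in _ID_COLUMNS]

    long = wide.melt(
        id_vars=list(_ID_COLUMNS),
        value_vars=trait_columns,
        var_name="trait",
        value_name="value",
    )

    n_before = long["value"].notna().sum()
    long["value"] = pd.to_numeric(long["value"], errors="coerce")
    n_coerced = n_before - long["value"].notna().sum()
    if n_coerced:
        logger.warning("%d malformed numeric cells coerced to missing", n_coerced)

    for col in ("year", "replicate"):
        long[col] = pd.to_numeric(long[col], errors="coerce").astype("Int64")
    for col in ("release_year", "row", "col"):
        long[col] = pd.to_numeric(long[col], errors="coerce").astype("Int64")
    long["genotype"] = long["genotype"].astype(str)
    long["location"] = long["location"].astype(str)
    long["management"] = long["management"].astype(str)

    return long[RECORD_COLUMNS].reset_index(drop=True)


def write_plot_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a long record table as a wide per-plot CSV (round-trippable)."""
    path = Path(path)
    if records.empty:
        pd.DataFrame(columns=list(_ID_COLUMNS)).to_csv(path, index=False)
        return
    wide = (
        records.drop_duplicates(subset=list(_ID_COLUMNS) + ["trait"])
        .set_index(list(_ID_COLUMNS) + ["trait"])["value"]
        .unstack("trait")
        .reset_index()
    )
    wide.columns.name = None
    wide.to_csv(path, index=False, na_rep="NA")


def read_cultivar_meta(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read cultivar metadata (genotype, name, release_year)."""
    meta = pd.read_csv(path)
    if column_map:
        meta = meta.rename(columns=dict(column_map))
    for col in ("genotype", "release_year"):
        if col not in meta.columns:
            raise ValueError(f"cultivar metadata is missing column {col!r}")
    if "name" not in meta.columns:
        meta["name"] = meta["genotype"]
    meta["genotype"] = meta["genotype"].astype(str)
    meta["release_year"] = pd.to_numeric(meta["release_year"]).astype(int)
    if meta["genotype"].duplicated().any():
        raise ValueError("duplicated genotype ids in cultivar metadata")
    return meta[["genotype", "name", "release_year"]]


def validate_records(records: pd.DataFrame) -> dict[str, int]:
    """Count invariant violations per rule without mutating the input.

    Rules
    -----
    unknown_trait
        trait not in the registry;
    bad_management
        label not among the nine realised management codes (or unparsable);
    disease_out_of_range
        disease score outside [0, 100];
    bad_replicate
        replicate not in {1, 2, 3};
    duplicate
        repeated (genotype, year, location, management, replicate, trait).
    """
    report: dict[str, int] = {}
    registry = trait_registry()

    report["unknown_trait"] = int((~records["trait"].isin(registry)).sum())

    def _bad_label(label: str) -> bool:
        if label in MANAGEMENT_LABELS:
            return False
        try:
            ManagementCode.parse(label)
        except ValueError:
            return True
        return True  # parsable but not a realised combination

    bad = records["management"].astype(str).map(_bad_label)
    report["bad_management"] = int(bad.sum())

    is_disease = records["trait"].isin(DISEASE_TRAITS)
    vals = records.loc[is_disease, "value"]
    report["disease_out_of_range"] = int(((vals < 0) | (vals > 100)).sum())

    rep = records["replicate"]
    report["bad_replicate"] = int((~rep.isin([1, 2, 3])).sum())

    key = ["genotype", "year", "location", "management", "replicate", "trait"]
    report["duplicate"] = int(records.duplicated(subset=key).sum())

    return report
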