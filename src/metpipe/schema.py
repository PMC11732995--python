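"""Canonical data model for plot-level multi-environment trial (MET) records.

The pipeline's in-memory container is a long ("tidy") :class:`pandas.DataFrame`
with one row per (plot, trait) observation and the columns listed in
:data:`RECORD_COLUMNS`.  The dataclasses here give names and validation to the
structured fields of that table: the three-way management code, the growing
condition (year x location x management -- the environmental unit of every
analysis), and cultivar metadata.

Trait names are controlled by a registry shipped with the package
(``data/trait_registry.yaml``); users can register additional traits at run
time with :func:`register_trait`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import yaml

__all__ = [
    "RECORD_COLUMNS",
    "MANAGEMENT_LABELS",
    "NITROGEN_LEVELS",
    "FUNGICIDE_LEVELS",
    "WATER_LEVELS",
    "DEFAULT_LOCATIONS",
    "DISEASE_TRAITS",
    "ManagementCode",
    "GrowingCondition",
    "CultivarMeta",
    "trait_registry",
    "register_trait",
    "is_disease_trait",
    "trait_unit",
]

#: Canonical columns of the long-format record table.
RECORD_COLUMNS = [
    "genotype",
    "release_year",
    "year",
    "location",
    "management",
    "replicate",
    "row",
    "col",
    "trait",
    "value",
]

NITROGEN_LEVELS = ("HN", "LN")  # 220 / 110 kg N per ha
FUNGICIDE_LEVELS = ("WF", "NF")  # with / without fungicide
WATER_LEVELS = ("RF", "IR", "RO")  # rain-fed / irrigated / rain-out shelter

#: The nine management codes realised in the trial network.  Irrigation was
#: applied only at one location (GGE) and the rain-out shelter only at another
#: (KIE), so not every combinatorial label occurs.
MANAGEMENT_LABELS = (
    "HN_WF_RF",
    "HN_NF_RF",
    "LN_WF_RF",
    "LN_NF_RF",
    "HN_WF_IR",
    "HN_NF_IR",
    "LN_WF_IR",
    "LN_NF_IR",
    "HN_WF_RO",
)

DEFAULT_LOCATIONS = ("GGE", "HAN", "KAL", "KIE", "QLB", "RHH")

#: The six visual fungal infection scores summed into the total fungal
#: infection (TFI) trait.
DISEASE_TRAITS = (
    "Stripe_rust",
    "Septoria",
    "Powdery_mildew",
    "Leaf_rust",
    "DTR",
    "Fusarium",
)


@dataclass(frozen=True)
class ManagementCode:
    """Three-treatment management code, e.g. ``HN_WF_RF``.

    nitrogen: ``HN`` (high, 220 kg N/ha) or ``LN`` (low, 110 kg N/ha);
    fungicide: ``WF`` (with) or ``NF`` (none);
    water: ``RF`` (rain-fed), ``IR`` (irrigated) or ``RO`` (rain-out shelter).
    """

    nitrogen: str
    fungicide: str
    water: str

    def __post_init__(self) -> None:
        if self.nitrogen not in NITROGEN_LEVELS:
            raise ValueError(f"unknown nitrogen level {self.nitrogen!r}")
        if self.fungicide not in FUNGICIDE_LEVELS:
            raise ValueError(f"unknown fungicide level {self.fungicide!r}")
        if self.water not in WATER_LEVELS:
            raise ValueError(f"unknown water level {self.water!r}")

    @property
    def label(self) -> str:
        return f"{self.nitrogen}_{self.fungicide}_{self.water}"

    @classmethod
    def parse(cls, label: str) -> "ManagementCode":
        parts = str(label).split("_")
        if len(parts) != 3:
            raise ValueError(f"malformed management label {label!r}")
        return cls(*parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class GrowingCondition:
    """One year x location x management combination (Y/L/M)."""

    year: int
    location: str
    management: ManagementCode

    @property
    def key(self) -> str:
        return f"{self.year}/{self.location}/{self.management.label}"

    @classmethod
    def parse(cls, key: str) -> "GrowingCondition":
        year, location, label = str(key).split("/")
        return cls(int(year), location, ManagementCode.parse(label))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.key


@dataclass(frozen=True)
class CultivarMeta:
    """Cultivar identity and its year of market release."""

    genotype: str
    name: str
    release_year: int


def _load_registry() -> dict:
    text = resources.files("metpipe.data").joinpath("trait_registry.yaml").read_text()
    return yaml.safe_load(text)["traits"]


_REGISTRY: dict | None = None


def trait_registry() -> dict:
    """Return the trait registry (trait name -> metadata dict)."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _load_registry()
    return copy.deepcopy(_REGISTRY)


def register_trait(
    name: str,
    full_name: str = "",
    source: str = "user",
    unit: str = "",
    nonnegative: bool = True,
    disease: bool = False,
) -> None:
    """Add a user trait to the in-memory registry (not persisted)."""
    global _REGISTRY
    trait_registry()  # ensure loaded
    assert _REGISTRY is not None
    _REGISTRY[name] = {
        "full_name": full_name or name,
        "source": source,
        "unit": unit,
        "nonnegative": bool(nonnegative),
        "disease": bool(disease),
    }


def is_disease_trait(name: str) -> bool:
    return bool(trait_registry().get(name, {}).get("disease", False))


def trait_unit(name: str) -> str:
    return str(trait_registry().get(name, {}).get("unit", ""))


def known_traits() -> tuple[str, ...]:
    return tuple(trait_registry())


def condition_keys(conditions: Iterable[GrowingCondition]) -> list[str]:
    return [c.key for c in conditions]
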