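"""End-to-end orchestration: simulate/load -> QC -> BLUEs -> analyses.

Every stage is a thin call into the corresponding module; the pipeline only
routes tables between them and writes CSV artifacts with a provenance
header (package version, seed, config hash) so a run can be reproduced
byte-for-byte from its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import blues as blues_mod
from . import consistency as cons_mod
from . import progress as prog_mod
from . import qc as qc_mod
from . import relimp
from . import simcompare
from . import stability as stab_mod
from .io import read_plot_table
from .sim import (make_demo_design, make_paper_like_design,
                  make_phase1_subset_design, simulate)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "StageError"]

DEFAULT_PROGRESS_TRAITS = [
    "Seedyield", "TGW", "Harvest_Index_bio", "Straw",
    "Grain_per_spike_bio", "Spike_number_bio",
]
DEFAULT_STABILITY_TRAITS = [
    "Seedyield", "TGW", "Harvest_Index_bio", "Straw",
    "Grain_per_spike_bio", "Spike_number_bio", "Crude_protein",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    out_dir: str = "metpipe_out"
    seed: int = 0
    #: input plot CSV; None = simulate
    input_csv: str | None = None
    #: "phase1_subset" or "paper_like" (used when simulating)
    design: str = "phase1_subset"
    n_genotypes: int | None = None
    stages: dict[str, bool] = field(default_factory=lambda: {
        "qc": True, "blues": True, "consistency": True,
        "progress": True, "stability": True, "compare": True,
    })
    consistency_trait: str = "Seedyield"
    consistency_groupings: list[list[str]] = field(
        default_factory=lambda: [[], ["management"], ["location"], ["year"]]
    )
    progress_traits: list[str] = field(
        default_factory=lambda: list(DEFAULT_PROGRESS_TRAITS))
    stability_traits: list[str] = field(
        default_factory=lambda: list(DEFAULT_STABILITY_TRAITS))
    si_names: list[str] = field(default_factory=lambda: list(stab_mod.INDEX_NAMES))
    tfi_mode: str = "mean_tfi"
    #: genotype x trait CSV of external crop-model outputs; None = skip
    sim_table_csv: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (where the outputs
        land does not change what was computed)."""
        keys = sorted(set(self.__dataclass_fields__) - {"out_dir"})
        blob = yaml.safe_dump({k: getattr(self, k) for k in keys},
                              sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages; return {artifact name: path}.

    Raises :class:`StageError` naming the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# metpipe {__version__} seed={config.seed} config={config.digest()}\n"
    artifacts: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        _write(df, path, header)
        artifacts[name] = path

    # --- input ----------------------------------------------------------
    truth = None
    try:
        if config.input_csv is not None:
            records = read_plot_table(config.input_csv)
        else:
            builders = {"phase1_subset": make_phase1_subset_design,
                        "paper_like": make_paper_like_design,
                        "demo": make_demo_design}
            if config.design not in builders:
                raise ValueError(f"unknown design {config.design!r}")
            kwargs = {"seed": config.seed}
            if config.n_genotypes is not None:
                kwargs["n_genotypes"] = config.n_genotypes
            sim_config = builders[config.design](**kwargs)
            records, truth = simulate(sim_config)
    except Exception as exc:  # noqa: BLE001
        raise StageError("input", exc)

    # --- qc --------------------------------------------------------------
    qc_report = {}
    if config.stages.get("qc", True):
        try:
            records, n_recoded = qc_mod.apply_range_rules(records)
            records, n_excluded = qc_mod.apply_sd_rule(records)
            records = qc_mod.compute_tfi(records)
            qc_report = {"n_recoded": int(n_recoded),
                         "n_excluded": int(n_excluded),
                         "n_records": int(len(records))}
            with open(out / "qc_report.json", "w") as fh:
                json.dump(qc_report, fh, indent=2)
            artifacts["qc_report"] = out / "qc_report.json"
        except Exception as exc:  # noqa: BLE001
            raise StageError("qc", exc)

    # --- blues -----------------------------------------------------------
    if not config.stages.get("blues", True):
        return artifacts
    needed = sorted(
        {config.consistency_trait, "TFI", *config.progress_traits,
         *config.stability_traits}
        & set(records["trait"].unique())
    )
    try:
        blue_table = blues_mod.build_blue_table(records, traits=needed)
        emit("blues", blue_table)
    except Exception as exc:  # noqa: BLE001
        raise StageError("blues", exc)

    meta = (
        records[["genotype", "release_year"]]
        .dropna().drop_duplicates("genotype")
    )
    meta["release_year"] = meta["release_year"].astype(int)

    # --- consistency -----------------------------------------------------
    if config.stages.get("consistency", True):
        try:
            pairs = cons_mod.pairwise_consistency(
                blue_table, config.consistency_trait)
            emit("consistency_pairs", pairs)
            summaries = []
            for factors in config.consistency_groupings:
                grouped = cons_mod.group_pairs(pairs, factors)
                summary = cons_mod.summarize_groups(grouped)
                summary.insert(0, "grouping", "-".join(factors) or "all")
                summaries.append(summary)
            emit("consistency_summary", pd.concat(summaries, ignore_index=True))
        except Exception as exc:  # noqa: BLE001
            raise StageError("consistency", exc)

    # --- progress --------------------------------------------------------
    if config.stages.get("progress", True):
        try:
            bp = prog_mod.bp_table(blue_table, meta, config.progress_traits)
            emit("bp_conditions", bp)
            reg = prog_mod.bp_regression(bp, response="Seedyield")
            emit("bp_regression", reg)
            wide = bp.pivot_table(index="condition", columns="trait",
                                  values="bp", aggfunc="first").dropna()
            regressors = [t for t in config.progress_traits if t != "Seedyield"]
            imp = relimp.lmg(wide["Seedyield"], wide[regressors])
            emit("bp_importance",
                 relimp.stacked_importance([("all", imp)]))
        except Exception as exc:  # noqa: BLE001
            raise StageError("progress", exc)

    # --- stability -------------------------------------------------------
    if config.stages.get("stability", True):
        try:
            si_tables = {}
            for trait in config.stability_traits:
                mat = stab_mod.build_trait_matrix(blue_table, trait)
                si_tables[trait] = stab_mod.stability_indices(mat)
            stacked = pd.concat(
                {t: tbl for t, tbl in si_tables.items()}, names=["trait"]
            ).reset_index()
            emit("stability_indices", stacked)

            genotypes = sorted(
                set.intersection(*(set(t.index) for t in si_tables.values()))
            )
            tfi = stab_mod.tfi_regressor(
                blue_table, genotypes, mode=config.tfi_mode)
            regs = []
            imps = []
            for si in config.si_names:
                reg = stab_mod.si_regression(
                    si_tables, si, response="Seedyield", tfi=tfi)
                regs.append(reg)
                data = pd.DataFrame(
                    {f"SI_{t}": si_tables[t][si] for t in si_tables}
                )
                data["TFI"] = tfi
                data = data.dropna()
                xcols = [c for c in data.columns if c != "SI_Seedyield"]
                imps.append(
                    (si, relimp.lmg(data["SI_Seedyield"], data[xcols])))
            emit("si_regression", pd.concat(regs, ignore_index=True))
            emit("si_importance", relimp.stacked_importance(imps))
        except Exception as exc:  # noqa: BLE001
            raise StageError("stability", exc)

    # --- compare ---------------------------------------------------------
    if config.stages.get("compare", True) and config.sim_table_csv is not None:
        try:
            sim_table = pd.read_csv(config.sim_table_csv, index_col=0)
            traits = [t for t in sim_table.columns]
            field_means = (
                blue_table[blue_table["trait"].isin(traits)]
                .groupby(["genotype", "trait"])["blue"].mean()
                .unstack("trait")
            )
            field_corr = simcompare.corr_table(field_means)
            sim_corr = simcompare.corr_table(sim_table)
            emit("corr_compare", simcompare.compare(field_corr, sim_corr))
        except Exception as exc:  # noqa: BLE001
            raise StageError("compare", exc)

    logger.info("pipeline finished: %d artifact(s) in %s", len(artifacts), out)
    return artifacts
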