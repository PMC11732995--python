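"""Synthetic multi-environment trial (MET) generator with known ground truth.

Emulates the statistical structure the downstream analyses assume: a cultivar
panel whose genotype main effects trend with year of release (breeding
progress), environment (year x location) main effects, additive management
shifts, genotype-specific G x E noise (so genotypes differ in true
stability), row/column field gradients, and bounded disease scores.

The observation model for an agronomic trait is

    y = grand_mean + g_i + slope * (release_year_i - midpoint)
        + e_condition + management_shift + gxe_{i,condition}
        + row_r + col_c + eps,

with ``gxe_{i,j} ~ N(0, sd_i)`` and ``sd_i`` drawn once per genotype from a
uniform range -- genotypes with a larger ``sd_i`` are truly less stable.
Disease scores are generated on the same latent additive scale and clamped
to [0, 100].

Everything is reproducible from ``SimConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import (
    DEFAULT_LOCATIONS,
    DISEASE_TRAITS,
    RECORD_COLUMNS,
    GrowingCondition,
    ManagementCode,
)

__all__ = [
    "TraitSpec",
    "DiseaseSpec",
    "SimConfig",
    "SimTruth",
    "simulate",
    "make_paper_like_design",
    "make_phase1_subset_design",
    "make_demo_design",
    "default_trait_specs",
    "default_disease_specs",
]


@dataclass
class TraitSpec:
    """Generative parameters for one agronomic trait (units of the trait)."""

    grand_mean: float
    genotype_sd: float
    env_sd: float
    residual_sd: float
    bp_slope: float = 0.0  # trait units per release year
    gxe_sd_range: tuple[float, float] = (0.0, 0.0)
    row_sd: float = 0.0
    col_sd: float = 0.0
    #: additive shift per management level present in the label,
    #: e.g. ``{"LN": -8.0, "NF": -4.0}``.
    management_shifts: dict[str, float] = field(default_factory=dict)
    #: loading in [-1, 1] on a shared latent genotype factor ("vigor"),
    #: inducing cross-trait genotype correlations rho_ab = l_a * l_b while
    #: preserving the marginal genotype_sd.  Captures e.g. the negative
    #: yield-protein (dilution) and positive yield-biomass relations.
    vigor_loading: float = 0.0

    def __post_init__(self) -> None:
        for name in ("genotype_sd", "env_sd", "residual_sd", "row_sd", "col_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.gxe_sd_range
        if lo < 0 or hi < lo:
            raise ValueError("gxe_sd_range must satisfy 0 <= lo <= hi")
        if not -1.0 <= self.vigor_loading <= 1.0:
            raise ValueError("vigor_loading must lie in [-1, 1]")


@dataclass
class DiseaseSpec:
    """Generative parameters for one 0-100 bounded infection score."""

    baseline: float
    genotype_sd: float
    env_sd: float
    residual_sd: float
    #: score units per release year; negative = newer cultivars more resistant
    genotype_resistance_trend: float = 0.0
    #: heavy-tail inflation of the residual (0 = Gaussian)
    overdispersion: float = 0.0
    management_shifts: dict[str, float] = field(default_factory=dict)


def default_trait_specs() -> dict[str, TraitSpec]:
    """Trait parameters sized to the observed ranges of German winter wheat.

    Yields in dt/ha, harvest index unitless, thousand-grain weight in g.
    The grain-yield breeding-progress slope of 0.37 dt/ha/year reflects the
    magnitude reported for long-term cultivar panels.
    """
    return {
        "Seedyield": TraitSpec(
            grand_mean=65.0, genotype_sd=5.0, env_sd=8.0, residual_sd=3.0,
            bp_slope=0.37, gxe_sd_range=(1.5, 4.5), row_sd=1.0, col_sd=1.0,
            management_shifts={"LN": -8.0, "NF": -4.0, "IR": 3.0, "RO": -6.0},
            vigor_loading=0.9,
        ),
        "TGW": TraitSpec(
            grand_mean=45.0, genotype_sd=3.0, env_sd=2.5, residual_sd=1.2,
            bp_slope=0.05, gxe_sd_range=(0.5, 1.5), row_sd=0.3, col_sd=0.3,
            management_shifts={"LN": -1.0, "NF": -0.8, "RO": -1.5},
            vigor_loading=0.3,
        ),
        "Harvest_Index_bio": TraitSpec(
            grand_mean=0.45, genotype_sd=0.03, env_sd=0.03, residual_sd=0.015,
            bp_slope=0.0015, gxe_sd_range=(0.005, 0.02),
            row_sd=0.004, col_sd=0.004,
            management_shifts={"LN": -0.01, "NF": -0.01, "RO": -0.02},
            vigor_loading=0.4,
        ),
        "Straw": TraitSpec(
            grand_mean=75.0, genotype_sd=6.0, env_sd=10.0, residual_sd=4.0,
            bp_slope=-0.10, gxe_sd_range=(2.0, 6.0), row_sd=1.2, col_sd=1.2,
            management_shifts={"LN": -8.0, "NF": -3.0, "IR": 4.0, "RO": -8.0},
            vigor_loading=0.6,
        ),
        "Grain_per_spike_bio": TraitSpec(
            grand_mean=35.0, genotype_sd=4.0, env_sd=4.0, residual_sd=2.0,
            bp_slope=0.05, gxe_sd_range=(1.0, 3.0), row_sd=0.5, col_sd=0.5,
            management_shifts={"LN": -2.0, "NF": -1.0},
            vigor_loading=0.3,
        ),
        "Spike_number_bio": TraitSpec(
            grand_mean=450.0, genotype_sd=40.0, env_sd=60.0, residual_sd=30.0,
            bp_slope=-0.5, gxe_sd_range=(15.0, 45.0), row_sd=8.0, col_sd=8.0,
            management_shifts={"LN": -50.0, "NF": -10.0, "RO": -40.0},
            vigor_loading=0.5,
        ),
        "Crude_protein": TraitSpec(
            grand_mean=13.0, genotype_sd=0.8, env_sd=1.0, residual_sd=0.4,
            bp_slope=-0.02, gxe_sd_range=(0.2, 0.6), row_sd=0.1, col_sd=0.1,
            management_shifts={"LN": -1.5, "NF": 0.2},
            vigor_loading=-0.7,
        ),
    }


def default_disease_specs() -> dict[str, DiseaseSpec]:
    """Infection-score parameters: modest natural pressure, resistance gain
    with release year, fungicide (WF) suppressing infection."""
    specs: dict[str, DiseaseSpec] = {}
    baselines = {
        "Stripe_rust": 12.0, "Septoria": 15.0, "Powdery_mildew": 8.0,
        "Leaf_rust": 10.0, "DTR": 6.0, "Fusarium": 4.0,
    }
    for name, base in baselines.items():
        specs[name] = DiseaseSpec(
            baseline=base, genotype_sd=4.0, env_sd=5.0, residual_sd=3.0,
            genotype_resistance_trend=-0.12, overdispersion=0.5,
            management_shifts={"WF": -0.6 * base, "LN": -1.0},
        )
    return specs


@dataclass
class SimConfig:
    """Full specification of one synthetic MET."""

    n_genotypes: int
    release_span: tuple[int, int]
    conditions: list[GrowingCondition]
    trait_specs: dict[str, TraitSpec]
    disease_specs: dict[str, DiseaseSpec] = field(default_factory=dict)
    replicates: int = 2
    #: per-condition-key replicate overrides (e.g. a 3-replicate site)
    replicate_overrides: dict[str, int] = field(default_factory=dict)
    #: per-condition-key genotype panels (indices into the genotype list);
    #: conditions absent from the map use the full panel
    panels: dict[str, np.ndarray] = field(default_factory=dict)
    #: fixed (n_rows, n_cols) grid for every condition; None = near-square
    layout: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genotypes < 1:
            raise ValueError("n_genotypes must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def genotypes(self) -> list[str]:
        width = max(3, len(str(self.n_genotypes - 1)))
        return [f"G{i:0{width}d}" for i in range(self.n_genotypes)]

    def replicates_for(self, key: str) -> int:
        return self.replicate_overrides.get(key, self.replicates)

    def panel_for(self, key: str) -> np.ndarray:
        return self.panels.get(key, np.arange(self.n_genotypes))


@dataclass
class SimTruth:
    """Ground truth underlying a simulated table."""

    release_year: pd.Series  # per genotype
    bp_slope: pd.Series  # per trait, trait units / year
    genotype_dev: pd.DataFrame  # genotype x trait: g_i (no trend)
    genotype_value: pd.DataFrame  # genotype x trait: mean + g_i + trend
    gxe_sd: pd.DataFrame  # genotype x trait: true stability sd
    env_effects: pd.DataFrame  # condition key x trait
    gxe: dict[str, pd.DataFrame]  # trait -> genotype x condition-key
    management_shift: pd.DataFrame  # condition key x trait
    row_effects: dict[str, np.ndarray]  # condition key -> per-row effects
    col_effects: dict[str, np.ndarray]

    def condition_means(self, trait: str) -> pd.DataFrame:
        """Expected plot value per (genotype, condition), noise removed."""
        base = self.genotype_value[trait]
        env = self.env_effects[trait] + self.management_shift[trait]
        out = self.gxe[trait].add(base, axis=0).add(env, axis=1)
        return out


def _management_shift(spec_shifts: dict[str, float], label: str) -> float:
    code = ManagementCode.parse(label)
    levels = (code.nitrogen, code.fungicide, code.water)
    return float(sum(spec_shifts.get(lv, 0.0) for lv in levels))


def simulate(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Draw one MET realisation; return (long record table, ground truth)."""
    rng = np.random.default_rng(config.seed)
    G = config.n_genotypes
    genotypes = config.genotypes
    y0, y1 = config.release_span
    release = np.rint(np.linspace(y0, y1, G)).astype(int)
    mid = 0.5 * (y0 + y1)

    keys = [c.key for c in config.conditions]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate growing conditions in config")
    C = len(keys)

    all_specs: dict[str, TraitSpec | DiseaseSpec] = {}
    all_specs.update(config.trait_specs)
    all_specs.update(config.disease_specs)
    traits = list(all_specs)

    # --- genotype- and condition-level draws, one block per trait ---------
    vigor = rng.normal(0.0, 1.0, G)  # shared latent genotype factor
    g_dev = {}
    gxe_sd = {}
    env = {}
    gxe = {}
    slope = {}
    gvalue = {}
    mshift = {}
    for t in traits:
        spec = all_specs[t]
        if isinstance(spec, TraitSpec):
            mean, gsd, esd = spec.grand_mean, spec.genotype_sd, spec.env_sd
            slope[t] = spec.bp_slope
            lo, hi = spec.gxe_sd_range
            loading = spec.vigor_loading
        else:
            mean, gsd, esd = spec.baseline, spec.genotype_sd, spec.env_sd
            slope[t] = spec.genotype_resistance_trend
            lo, hi = (0.0, 0.0)
            loading = 0.0
        if gsd > 0:
            own = rng.normal(0.0, 1.0, G)
            g_dev[t] = gsd * (loading * vigor
                              + math.sqrt(1.0 - loading ** 2) * own)
        else:
            g_dev[t] = np.zeros(G)
        gxe_sd[t] = rng.uniform(lo, hi, G) if hi > 0 else np.zeros(G)
        env[t] = rng.normal(0.0, esd, C) if esd > 0 else np.zeros(C)
        sd_mat = np.tile(gxe_sd[t][:, None], (1, C))
        gxe[t] = np.where(sd_mat > 0, rng.normal(0.0, 1.0, (G, C)) * sd_mat, 0.0)
        gvalue[t] = mean + g_dev[t] + slope[t] * (release - mid)
        mshift[t] = np.array(
            [_management_shift(spec.management_shifts, c.management.label)
             for c in config.conditions]
        )

    # --- per-condition field layout and plot noise ------------------------
    frames = []
    row_eff_store: dict[str, np.ndarray] = {}
    col_eff_store: dict[str, np.ndarray] = {}
    for j, cond in enumerate(config.conditions):
        key = keys[j]
        panel = np.asarray(config.panel_for(key))
        reps = config.replicates_for(key)
        n_plots = panel.size * reps
        if config.layout is not None:
            n_rows, n_cols = config.layout
            if n_rows * n_cols < n_plots:
                raise ValueError(
                    f"layout {config.layout} too small for {n_plots} plots in {key}"
                )
        else:
            n_cols = int(math.ceil(math.sqrt(n_plots)))
            n_rows = int(math.ceil(n_plots / n_cols))

        # replicate blocks occupy consecutive row bands; genotypes are
        # re-randomised within each block (randomised complete block design)
        order = np.concatenate([rng.permutation(panel) for _ in range(reps)])
        rep_idx = np.repeat(np.arange(1, reps + 1), panel.size)
        plot_idx = np.arange(n_plots)
        prow = plot_idx // n_cols + 1
        pcol = plot_idx % n_cols + 1

        cond_frames = {}
        for t in traits:
            spec = all_specs[t]
            if isinstance(spec, TraitSpec):
                rsd, csd, esd_resid = spec.row_sd, spec.col_sd, spec.residual_sd
            else:
                rsd, csd, esd_resid = 0.0, 0.0, spec.residual_sd
            r_eff = rng.normal(0.0, rsd, n_rows) if rsd > 0 else np.zeros(n_rows)
            c_eff = rng.normal(0.0, csd, n_cols) if csd > 0 else np.zeros(n_cols)
            if t == traits[0]:
                row_eff_store[key] = r_eff
                col_eff_store[key] = c_eff
            if esd_resid > 0:
                eps = rng.normal(0.0, esd_resid, n_plots)
                if isinstance(spec, DiseaseSpec) and spec.overdispersion > 0:
                    infl = 1.0 + spec.overdispersion * np.abs(
                        rng.normal(0.0, 1.0, n_plots)
                    )
                    eps = eps * infl
            else:
                eps = np.zeros(n_plots)
            vals = (
                gvalue[t][order]
                + env[t][j]
                + mshift[t][j]
                + gxe[t][order, j]
                + r_eff[prow - 1]
                + c_eff[pcol - 1]
                + eps
            )
            if isinstance(spec, DiseaseSpec):
                vals = np.clip(vals, 0.0, 100.0)
            cond_frames[t] = vals

        base = pd.DataFrame(
            {
                "genotype": np.array(genotypes)[order],
                "release_year": release[order],
                "year": cond.year,
                "location": cond.location,
                "management": cond.management.label,
                "replicate": rep_idx,
                "row": prow,
                "col": pcol,
            }
        )
        long = base.loc[base.index.repeat(len(traits))].reset_index(drop=True)
        long["trait"] = np.tile(np.array(traits, dtype=object), n_plots)
        long["value"] = np.column_stack([cond_frames[t] for t in traits]).ravel()
        frames.append(long)

    records = pd.concat(frames, ignore_index=True)[RECORD_COLUMNS]
    for c in ("release_year", "year", "replicate", "row", "col"):
        records[c] = records[c].astype("Int64")

    gidx = pd.Index(genotypes, name="genotype")
    kidx = pd.Index(keys, name="condition")
    truth = SimTruth(
        release_year=pd.Series(release, index=gidx, name="release_year"),
        bp_slope=pd.Series(slope, name="bp_slope"),
        genotype_dev=pd.DataFrame(g_dev, index=gidx),
        genotype_value=pd.DataFrame(gvalue, index=gidx),
        gxe_sd=pd.DataFrame(gxe_sd, index=gidx),
        env_effects=pd.DataFrame(env, index=kidx),
        gxe={t: pd.DataFrame(gxe[t], index=gidx, columns=kidx) for t in traits},
        management_shift=pd.DataFrame(mshift, index=kidx),
        row_effects=row_eff_store,
        col_effects=col_eff_store,
    )
    return records, truth


def _mgmt(label: str) -> ManagementCode:
    return ManagementCode.parse(label)


def make_paper_like_design(
    n_genotypes: int = 228, seed: int = 0
) -> SimConfig:
    """Config mirroring the real trial network's unbalanced structure.

    29 year x location environments over 2015-2020 and six German sites;
    nine managements: four nitrogen x fungicide combinations rain-fed
    everywhere, the irrigated variants only at GGE (2015/2018/2019, where
    all managements were irrigated alongside one rain-fed check), and the
    rain-out shelter only at KIE (2016/2017/2019).  The phase-I panel holds
    220 cultivars (2015-2017); later seasons use a 52-cultivar subset.
    KIE rain-fed conditions carry three replicates instead of two.
    """
    locations = DEFAULT_LOCATIONS
    envs: list[tuple[int, str]] = []
    for year in (2015, 2016, 2017):
        envs += [(year, loc) for loc in locations]
    envs += [(2018, loc) for loc in ("HAN", "KIE", "QLB")]
    envs += [(2019, loc) for loc in locations]
    envs += [(2020, loc) for loc in ("KIE", "QLB")]
    assert len(envs) == 29

    base_rf = ["HN_WF_RF", "HN_NF_RF", "LN_WF_RF", "LN_NF_RF"]
    conditions: list[GrowingCondition] = []
    for year, loc in envs:
        if loc == "GGE" and year in (2015, 2018, 2019):
            labels = ["HN_WF_IR", "HN_NF_IR", "LN_WF_IR", "LN_NF_IR", "HN_WF_RF"]
        elif loc == "KIE" and year in (2016, 2017, 2019):
            labels = base_rf + ["HN_WF_RO"]
        else:
            labels = list(base_rf)
        conditions += [GrowingCondition(year, loc, _mgmt(lb)) for lb in labels]

    phase1 = np.arange(220)
    rng = np.random.default_rng(seed)
    phase2 = np.sort(rng.choice(phase1, size=52, replace=False))

    panels: dict[str, np.ndarray] = {}
    overrides: dict[str, int] = {}
    for cond in conditions:
        if cond.year >= 2018:
            panels[cond.key] = phase2
        else:
            panels[cond.key] = phase1
        if cond.location == "KIE":
            if cond.management.water == "RF" and cond.year <= 2019:
                overrides[cond.key] = 3
            if cond.management.water == "RO" and cond.year == 2019:
                overrides[cond.key] = 3

    return SimConfig(
        n_genotypes=n_genotypes,
        release_span=(1963, 2016),
        conditions=conditions,
        trait_specs=default_trait_specs(),
        disease_specs=default_disease_specs(),
        replicates=2,
        replicate_overrides=overrides,
        panels=panels,
        seed=seed,
    )


def make_demo_design(n_genotypes: int = 60, seed: int = 0) -> SimConfig:
    """A quick demonstration design: 2 years x 2 locations x 3 rain-fed
    managements = 12 growing conditions."""
    conditions = [
        GrowingCondition(year, loc, _mgmt(lb))
        for year in (2015, 2016)
        for loc in ("GGE", "HAN")
        for lb in ("HN_WF_RF", "HN_NF_RF", "LN_NF_RF")
    ]
    return SimConfig(
        n_genotypes=n_genotypes,
        release_span=(1963, 2016),
        conditions=conditions,
        trait_specs=default_trait_specs(),
        disease_specs=default_disease_specs(),
        replicates=2,
        seed=seed,
    )


def make_phase1_subset_design(n_genotypes: int = 220, seed: int = 0) -> SimConfig:
    """The balanced analysis subset: 3 years x 5 locations x 3 rain-fed
    managements = 45 growing conditions, 220 cultivars, two replicates
    (three at KIE)."""
    conditions = [
        GrowingCondition(year, loc, _mgmt(lb))
        for year in (2015, 2016, 2017)
        for loc in ("GGE", "HAN", "KAL", "KIE", "QLB")
        for lb in ("HN_WF_RF", "HN_NF_RF", "LN_NF_RF")
    ]
    overrides = {c.key: 3 for c in conditions if c.location == "KIE"}
    return SimConfig(
        n_genotypes=n_genotypes,
        release_span=(1963, 2016),
        conditions=conditions,
        trait_specs=default_trait_specs(),
        disease_specs=default_disease_specs(),
        replicates=2,
        replicate_overrides=overrides,
        seed=seed,
    )
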