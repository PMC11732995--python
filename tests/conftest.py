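import numpy as np
import pandas as pd
import pytest

from metpipe.schema import GrowingCondition, ManagementCode
from metpipe.sim import SimConfig, TraitSpec, simulate


def make_conditions(n_years=2, locations=("GGE", "HAN"),
                    managements=("HN_WF_RF", "LN_NF_RF")):
    return [
        GrowingCondition(2015 + y, loc, ManagementCode.parse(m))
        for y in range(n_years)
        for loc in locations
        for m in managements
    ]


@pytest.fixture(scope="session")
def small_sim():
    """30 genotypes x 8 conditions x 2 reps, one yield-like trait with
    moderate noise; shared across read-only tests."""
    spec = TraitSpec(
        grand_mean=60.0, genotype_sd=5.0, env_sd=6.0, residual_sd=2.0,
        bp_slope=0.3, gxe_sd_range=(1.0, 3.0), row_sd=1.0, col_sd=1.0,
        management_shifts={"LN": -6.0},
    )
    cfg = SimConfig(
        n_genotypes=30, release_span=(1963, 2016),
        conditions=make_conditions(),
        trait_specs={"Seedyield": spec}, seed=11,
    )
    records, truth = simulate(cfg)
    return cfg, records, truth


@pytest.fixture()
def toy_records():
    """Tiny deterministic long table: 3 genotypes x 1 condition x 2 reps."""
    rows = []
    for g, base in (("A", 50.0), ("B", 55.0), ("C", 60.0)):
        for rep in (1, 2):
            rows.append({
                "genotype": g, "release_year": 1990, "year": 2015,
                "location": "GGE", "management": "HN_WF_RF",
                "replicate": rep, "row": rep, "col": ord(g) - 64,
                "trait": "Seedyield", "value": base + 0.5 * rep,
            })
    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
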