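"""SMA trait consistency, pair grouping and the ANOVA + LSD letters."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metpipe.consistency import (
    anova_lsd,
    group_pairs,
    pairwise_consistency,
    sma_fit,
    summarize_groups,
)


def blue_table_from_matrix(mat: pd.DataFrame, trait="Seedyield"):
    """condition columns are 'year/loc/mgmt' keys."""
    rows = []
    for cond in mat.columns:
        year, loc, mgmt = cond.split("/")
        for g, v in mat[cond].items():
            rows.append({"genotype": g, "year": int(year), "location": loc,
                         "management": mgmt, "trait": trait, "blue": v,
                         "fallback": "none"})
    return pd.DataFrame(rows)


class TestSma:
    def test_exact_proportional(self):
        x = np.arange(1.0, 11.0)
        res = sma_fit(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r2 == pytest.approx(1.0)

    def test_independent_noise_r2_near_zero(self):
        rng = np.random.default_rng(0)
        res = sma_fit(rng.normal(size=10_000), rng.normal(size=10_000))
        assert res.r2 < 0.01

    def test_axis_swap_inverts_slope(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = 1.5 * x + rng.normal(scale=0.5, size=50)
        a = sma_fit(x, y)
        b = sma_fit(y, x)
        assert a.slope * b.slope == pytest.approx(1.0)
        assert a.r2 == pytest.approx(b.r2, abs=1e-12)

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        y = -0.7 * x + rng.normal(size=200)
        res = sma_fit(x, y)
        r = stats.pearsonr(x, y).statistic
        assert res.r2 == pytest.approx(r * r, abs=1e-12)
        assert res.slope < 0

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            sma_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_property_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20) + 0.5 * x
        a, b = sma_fit(x, y), sma_fit(y, x)
        assert a.r2 == pytest.approx(b.r2, abs=1e-12)
        assert a.r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)


class TestPairwise:
    def _matrix(self, n_cond=4, n_gen=12, seed=0):
        rng = np.random.default_rng(seed)
        cols = [f"{2015 + i % 2}/L{i}/HN_WF_RF" for i in range(n_cond)]
        return pd.DataFrame(rng.normal(60, 5, (n_gen, n_cond)),
                            index=[f"g{i}" for i in range(n_gen)],
                            columns=cols)

    def test_two_conditions_one_pair(self):
        bt = blue_table_from_matrix(self._matrix(n_cond=2))
        pairs = pairwise_consistency(bt, "Seedyield")
        assert len(pairs) == 1

    def test_all_unordered_pairs(self):
        k = 6
        bt = blue_table_from_matrix(self._matrix(n_cond=k))
        pairs = pairwise_consistency(bt, "Seedyield")
        assert len(pairs) == k * (k - 1) // 2

    def test_missing_genotype_reduces_n(self):
        mat = self._matrix(n_cond=2)
        mat.iloc[0, 0] = np.nan
        bt = blue_table_from_matrix(mat)
        bt = bt[bt["blue"].notna()]
        pairs = pairwise_consistency(bt, "Seedyield")
        assert pairs["n"].iloc[0] == len(mat) - 1

    def test_r2_matches_direct_pearson(self):
        mat = self._matrix(n_cond=3, seed=5)
        bt = blue_table_from_matrix(mat)
        pairs = pairwise_consistency(bt, "Seedyield")
        for _, row in pairs.iterrows():
            r = np.corrcoef(mat[row["condition_a"]],
                            mat[row["condition_b"]])[0, 1]
            assert row["r2_sma"] == pytest.approx(r * r, abs=1e-12)


class TestGroupPairs:
    def _pairs(self):
        conds = [f"{y}/{lo}/{m}" for y in (2015, 2016) for lo in ("GGE", "HAN")
                 for m in ("HN_WF_RF", "LN_NF_RF")]
        rows = [
            {"condition_a": a, "condition_b": b, "r2_sma": 0.5, "n": 10}
            for a, b in itertools.combinations(conds, 2)
        ]
        return pd.DataFrame(rows)

    def test_management_grouping_level(self):
        pairs = pd.DataFrame([{
            "condition_a": "2015/GGE/HN_WF_RF",
            "condition_b": "2016/HAN/HN_WF_RF",
            "r2_sma": 0.4, "n": 10,
        }])
        out = group_pairs(pairs, ["management"])
        assert out["level"].tolist() == ["HN_WF_RF"]

    def test_year_grouping_drops_cross_year(self):
        pairs = pd.DataFrame([{
            "condition_a": "2015/GGE/HN_WF_RF",
            "condition_b": "2016/HAN/HN_WF_RF",
            "r2_sma": 0.4, "n": 10,
        }])
        assert group_pairs(pairs, ["year"]).empty

    def test_double_grouping_keeps_only_year_contrasts(self):
        out = group_pairs(self._pairs(), ["management", "location"])
        for _, row in out.iterrows():
            ya, la, ma = row["condition_a"].split("/")
            yb, lb, mb = row["condition_b"].split("/")
            assert la == lb and ma == mb and ya != yb

    def test_levels_partition_subset_of_pool(self):
        pairs = self._pairs()
        out = group_pairs(pairs, ["management"])
        assert len(out) <= len(pairs)
        # no pair in two levels: grouping key is a function of the pair
        key = out["condition_a"] + "|" + out["condition_b"]
        assert key.is_unique

    def test_unknown_factor_raises(self):
        with pytest.raises(ValueError, match="grouping"):
            group_pairs(self._pairs(), ["treatment"])


class TestAnovaLsd:
    def test_identical_groups_share_letter(self):
        p, letters = anova_lsd({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert p > 0.05
        assert letters == {"a": "a", "b": "a"}

    def test_clearly_separated_groups(self):
        p, letters = anova_lsd({"lo": [0.0] * 4, "hi": [10.0] * 4})
        assert p < 1e-6
        assert {letters["hi"], letters["lo"]} == {"a", "b"}
        assert letters["hi"] == "a"  # higher mean gets the first letter

    def test_overlap_pattern_a_ab_b(self):
        """Middle group within the LSD of both extremes, extremes differ.

        Hand oracle: 5 values per group with within-group sd 0.7906,
        pooled over 3 groups -> LSD = t(0.975, 12) * sd * sqrt(2/5) = 1.089;
        mean gaps of 1.0 (ns) and 2.0 (significant)."""
        base = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        groups = {"A": base + 2.0, "B": base + 1.0, "C": base + 0.0}
        p, letters = anova_lsd(groups)
        assert p < 0.05
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    def test_tiny_level_excluded(self):
        p, letters = anova_lsd({"a": [1.0, 2.0, 1.5], "b": [1.1, 2.2, 1.4],
                                "c": [5.0]})
        assert "c" not in letters

    def test_single_usable_level_raises(self):
        with pytest.raises(ValueError):
            anova_lsd({"a": [1.0, 2.0], "b": [3.0]})


def test_summarize_groups_orders_and_letters():
    rng = np.random.default_rng(0)
    rows = []
    for lv, mu in (("HN_WF_RF", 0.6), ("LN_NF_RF", 0.3)):
        for i in range(8):
            rows.append({"condition_a": f"2015/GGE/{lv}",
                         "condition_b": f"2016/HAN/{lv}",
                         "r2_sma": np.clip(rng.normal(mu, 0.03), 0, 1),
                         "n": 10, "level": lv})
    out = summarize_groups(pd.DataFrame(rows))
    assert (out["max"] >= out["mean"]).all()
    assert (out["mean"] >= out["min"]).all()
    hi = out.set_index("level").loc["HN_WF_RF"]
    lo = out.set_index("level").loc["LN_NF_RF"]
    assert hi["letter"] != lo["letter"]
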