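"""Nine stability indices against a brute-force oracle, their algebraic
identities, and the stability regression."""

import numpy as np
import pandas as pd
import pytest

from metpipe.stability import (
    INDEX_DIRECTION,
    INDEX_NAMES,
    build_trait_matrix,
    si_regression,
    stability_indices,
    tfi_regressor,
)

from _oracles import stability_oracle


def as_matrix(x, prefix="g"):
    x = np.asarray(x, float)
    G, E = x.shape
    return pd.DataFrame(x, index=[f"{prefix}{i}" for i in range(G)],
                        columns=[f"2015/L{j}/HN_WF_RF" for j in range(E)])


FIXTURE_5X4 = np.array([
    [62.1, 55.3, 70.2, 48.9],
    [60.0, 58.1, 64.5, 52.3],
    [71.4, 49.8, 69.9, 46.5],
    [58.2, 57.0, 61.1, 55.4],
    [65.5, 52.2, 75.0, 41.0],
])


class TestIndices:
    def test_matches_brute_force_oracle(self):
        si = stability_indices(as_matrix(FIXTURE_5X4))
        oracle = stability_oracle(FIXTURE_5X4)
        for name in INDEX_NAMES:
            np.testing.assert_allclose(si[name], oracle[name], atol=1e-10,
                                       err_msg=name)

    def test_additive_matrix_no_interaction(self):
        a = np.arange(10)[:, None] * 2.0
        c = np.arange(8)[None, :] * 3.0
        si = stability_indices(as_matrix(50.0 + a + c))
        np.testing.assert_allclose(si["W_i"], 0.0, atol=1e-18)
        np.testing.assert_allclose(si["s2_di"], 0.0, atol=1e-18)
        np.testing.assert_allclose(si["S4_i"], 0.0, atol=1e-18)
        np.testing.assert_allclose(si["b_i"], 1.0, atol=1e-12)
        np.testing.assert_allclose(si["r2_i"], 1.0, atol=1e-12)

    def test_best_genotype_has_zero_superiority(self):
        rng = np.random.default_rng(0)
        x = rng.normal(60, 5, (6, 5))
        x[2] = x.max(axis=0) + 1.0  # best everywhere
        si = stability_indices(as_matrix(x))
        assert si["P_i"].iloc[2] == pytest.approx(0.0, abs=1e-18)
        assert (si["P_i"].drop(si.index[2]) > 0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_algebraic_identities(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(60, 5, (20, 10))
        si = stability_indices(as_matrix(x))
        G, E = x.shape
        inter = x - x.mean(1, keepdims=True) - x.mean(0) + x.mean()
        ss_int = (inter ** 2).sum()
        assert si["W_i"].sum() == pytest.approx(ss_int, rel=1e-12)
        assert si["b_i"].mean() == pytest.approx(1.0, abs=1e-9)
        assert si["sigma2_i"].mean() == pytest.approx(
            ss_int / ((G - 1) * (E - 1)), rel=1e-9)

    def test_location_and_scale_behaviour(self):
        rng = np.random.default_rng(3)
        x = rng.normal(60, 5, (8, 6))
        base = stability_indices(as_matrix(x))
        shifted = stability_indices(as_matrix(x + 17.0))
        scaled = stability_indices(as_matrix(x * 3.0))
        for name in INDEX_NAMES:
            np.testing.assert_allclose(shifted[name], base[name], atol=1e-8,
                                       err_msg=f"shift {name}")
        for name in ("W_i", "s2_di", "S2_xi", "D2_i", "P_i"):
            np.testing.assert_allclose(scaled[name], 9.0 * base[name],
                                       rtol=1e-9, err_msg=f"scale {name}")
        for name in ("b_i", "r2_i", "S4_i"):
            np.testing.assert_allclose(scaled[name], base[name], rtol=1e-9,
                                       err_msg=f"scale {name}")

    def test_direction_metadata_on_constructed_pair(self):
        """A flat genotype and an erratic one: every 'smaller = stable'
        index must rank the flat one as more stable."""
        rng = np.random.default_rng(4)
        E = 12
        env = np.linspace(-5, 5, E)
        stable = 60.0 + env  # perfectly average response
        erratic = 60.0 + env + rng.normal(0, 6, E)
        filler = 58.0 + env[None, :] + rng.normal(0, 0.5, (4, E))
        x = np.vstack([stable, erratic, filler])
        si = stability_indices(as_matrix(x))
        assert set(INDEX_DIRECTION) == set(INDEX_NAMES)
        for name, direction in INDEX_DIRECTION.items():
            if direction == "smaller":
                assert si[name].iloc[0] < si[name].iloc[1], name
        assert abs(si["b_i"].iloc[0] - 1.0) < abs(si["b_i"].iloc[1] - 1.0)
        assert si["r2_i"].iloc[0] > si["r2_i"].iloc[1]

    def test_degenerate_dimensions(self):
        rng = np.random.default_rng(5)
        two_env = stability_indices(as_matrix(rng.normal(0, 1, (5, 2))))
        assert two_env["s2_di"].isna().all()
        two_gen = stability_indices(as_matrix(rng.normal(0, 1, (2, 5))))
        assert two_gen["sigma2_i"].isna().all()


class TestBuildTraitMatrix:
    def _blue_table(self, mat):
        rows = []
        for cond in mat.columns:
            y, lo, m = cond.split("/")
            for g, v in mat[cond].items():
                if pd.isna(v):
                    continue
                rows.append({"genotype": g, "year": int(y), "location": lo,
                             "management": m, "trait": "Seedyield",
                             "blue": v, "fallback": "none"})
        return pd.DataFrame(rows)

    def test_full_table_no_drops(self):
        mat = as_matrix(np.arange(20.0).reshape(5, 4))
        out = build_trait_matrix(self._blue_table(mat), "Seedyield")
        assert out.shape == (5, 4)

    def test_incomplete_genotype_dropped(self):
        mat = as_matrix(np.arange(20.0).reshape(5, 4))
        mat.iloc[1, 2] = np.nan
        out = build_trait_matrix(self._blue_table(mat), "Seedyield")
        assert list(out.index) == ["g0", "g2", "g3", "g4"]

    def test_too_few_survivors_raise(self):
        mat = as_matrix(np.arange(20.0).reshape(5, 4))
        mat.iloc[:3, 0] = np.nan
        with pytest.raises(ValueError):
            build_trait_matrix(self._blue_table(mat), "Seedyield")


class TestTfiRegressor:
    def _blue_table_tfi(self, mat):
        rows = []
        for cond in mat.columns:
            y, lo, m = cond.split("/")
            for g, v in mat[cond].items():
                rows.append({"genotype": g, "year": int(y), "location": lo,
                             "management": m, "trait": "TFI", "blue": v,
                             "fallback": "none"})
        return pd.DataFrame(rows)

    def test_constant_tfi_mean_mode(self):
        mat = as_matrix(np.full((4, 3), 5.0))
        vec = tfi_regressor(self._blue_table_tfi(mat), list(mat.index))
        np.testing.assert_allclose(vec, 5.0)

    def test_mean_mode_equals_subset_mean(self):
        rng = np.random.default_rng(1)
        mat = as_matrix(rng.uniform(0, 40, (5, 4)))
        subset = list(mat.columns[:2])
        vec = tfi_regressor(self._blue_table_tfi(mat), list(mat.index),
                            conditions=subset)
        np.testing.assert_allclose(vec, mat[subset].mean(axis=1), atol=1e-12)

    def test_si_of_tfi_additive_is_zero(self):
        a = np.arange(5.0)[:, None]
        c = np.arange(4.0)[None, :]
        mat = as_matrix(10.0 + a + c)
        vec = tfi_regressor(self._blue_table_tfi(mat), list(mat.index),
                            mode="si_of_tfi", si_name="W_i")
        np.testing.assert_allclose(vec, 0.0, atol=1e-18)

    def test_no_tfi_raises(self):
        bt = pd.DataFrame({"genotype": ["a"], "year": [2015],
                           "location": ["GGE"], "management": ["HN_WF_RF"],
                           "trait": ["Seedyield"], "blue": [1.0],
                           "fallback": ["none"]})
        with pytest.raises(ValueError, match="TFI"):
            tfi_regressor(bt, ["a"])


class TestSiRegression:
    def _tables(self, G=40, seed=0, exact=True):
        rng = np.random.default_rng(seed)
        traits = ["TGW", "Harvest_Index_bio", "Straw",
                  "Grain_per_spike_bio", "Spike_number_bio"]
        coef = dict(zip(traits, [0.5, 2.0, -0.3, 0.8, 0.1]))
        idx = [f"g{i:02d}" for i in range(G)]
        tables = {}
        parts = {}
        for t in traits:
            w = rng.uniform(0.5, 5.0, G)
            parts[t] = w
            tables[t] = pd.DataFrame({"W_i": w}, index=idx)
        gy = 1.0 + sum(coef[t] * parts[t] for t in traits)
        if not exact:
            gy = gy + rng.normal(0, 0.2, G)
        tables["Seedyield"] = pd.DataFrame({"W_i": gy}, index=idx)
        return tables, coef

    def test_exact_linear_combination(self):
        tables, coef = self._tables()
        out = si_regression(tables, "W_i").set_index("term")
        assert out["r2_full"].iloc[0] == pytest.approx(1.0, abs=1e-10)
        for t, b in coef.items():
            assert out.loc[f"SI_{t}", "beta"] == pytest.approx(b, abs=1e-8)

    def test_nine_indices_nine_models(self):
        rng = np.random.default_rng(2)
        x = {t: as_matrix(rng.normal(60, 5, (30, 8)), prefix="g")
             for t in ["Seedyield", "TGW"]}
        tables = {t: stability_indices(m) for t, m in x.items()}
        fits = [si_regression(tables, si) for si in INDEX_NAMES]
        assert len(fits) == 9
        assert all(not f.empty for f in fits)

    def test_permuted_response_low_r2(self):
        tables, _ = self._tables(G=200, exact=True)
        rng = np.random.default_rng(9)
        gy = tables["Seedyield"]["W_i"].to_numpy().copy()
        rng.shuffle(gy)
        tables["Seedyield"] = pd.DataFrame({"W_i": gy},
                                           index=tables["Seedyield"].index)
        out = si_regression(tables, "W_i")
        assert out["r2_full"].iloc[0] < 0.1

    def test_tfi_term_included(self):
        tables, _ = self._tables()
        tfi = pd.Series(np.linspace(0, 30, 40),
                        index=tables["Seedyield"].index, name="TFI")
        out = si_regression(tables, "W_i", tfi=tfi)
        assert "TFI" in out["term"].values
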