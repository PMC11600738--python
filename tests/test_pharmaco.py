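import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bandscape import pharmaco as ph
from bandscape.datatypes import DrugResponseTable, FeatureMatrix
from bandscape.simulate import DrugConfig, SimulationConfig, simulate_drug_response, stage_rngs

finite_floats = st.floats(-50, 50, allow_nan=False)


class TestGlassDelta:
    def test_unit_sd_groups(self):
        mean_diff, dp, dn = ph.glass_delta([-3, -2, -1], [0, 1, 2])
        assert mean_diff == pytest.approx(-3.0)
        assert dp == pytest.approx(3.0)
        assert dn == pytest.approx(3.0)

    def test_identical_groups_zero(self):
        mean_diff, dp, dn = ph.glass_delta([1, 2, 3], [1, 2, 3])
        assert mean_diff == 0.0 and dp == 0.0 and dn == 0.0

    def test_constant_group_flagged_nan(self):
        mean_diff, dp, dn = ph.glass_delta([1, 1, 1], [0, 1, 2])
        assert np.isnan(dp) and np.isfinite(dn)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(finite_floats, min_size=2, max_size=10),
        st.lists(finite_floats, min_size=2, max_size=10),
    )
    def test_matches_direct_formula(self, pos, neg):
        mean_diff, dp, dn = ph.glass_delta(pos, neg)
        md = np.mean(pos) - np.mean(neg)
        assert mean_diff == pytest.approx(md, abs=1e-12)
        sd_pos = np.std(pos, ddof=1)
        if sd_pos > 0:
            assert dp == pytest.approx(abs(md) / sd_pos, abs=1e-12)


class TestPointBiserial:
    def test_reference_value(self):
        r, _, _ = ph.point_biserial([0, 0, 1, 1], [1, 2, 3, 4])
        assert r == pytest.approx(0.894, abs=5e-4)

    @pytest.mark.parametrize(
        "r,expected",
        [(0.05, "negligible"), (0.10, "small"), (0.30, "medium"), (0.37, "large"), (-0.5, "large")],
    )
    def test_magnitude_boundaries(self, r, expected):
        assert ph.magnitude_of_r(r) == expected

    def test_ci_undefined_below_four(self):
        r, (lo, hi), _ = ph.point_biserial([0, 1, 1], [1.0, 2.0, 3.0])
        assert np.isfinite(r)
        assert np.isnan(lo) and np.isnan(hi)

    def test_null_r_small_at_large_n(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ind = rng.integers(0, 2, 1000)
            vals = rng.normal(size=1000)
            r, _, _ = ph.point_biserial(ind, vals)
            hits += abs(r) < 0.08
        assert hits >= 95

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(1, 9), st.lists(finite_floats, min_size=10, max_size=10, unique=True))
    def test_matches_pearson_formula(self, n_pos, values):
        ind = np.array([1] * n_pos + [0] * (10 - n_pos))
        vals = np.asarray(values)
        r, (lo, hi), _ = ph.point_biserial(ind, vals)
        rr = np.corrcoef(ind, vals)[0, 1]
        assert r == pytest.approx(rr, abs=1e-12)
        z = np.arctanh(rr)
        se = 1 / np.sqrt(10 - 3)
        assert lo == pytest.approx(np.tanh(z - 1.959963984540054 * se), abs=1e-9)


class TestMannWhitney:
    def test_exact_small_sample(self):
        assert ph.mw_group_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_singletons(self):
        assert ph.mw_group_test([1.0], [1.0]) == pytest.approx(1.0)

    def test_one_sided_halves_two_sided_without_ties(self):
        two = ph.mw_group_test([1, 2, 3], [4, 5, 6], "two-sided")
        one = ph.mw_group_test([1, 2, 3], [4, 5, 6], "less")
        assert one == pytest.approx(two / 2)


def _response_table(y, lines, drug="D1", screen="S1"):
    return DrugResponseTable(
        pd.DataFrame(
            {"cell_line": lines, "drug": drug, "screen_id": screen, "log10_ic50": y}
        )
    )


class TestElasticNet:
    def test_planted_effect_recovered_with_bounded_shrinkage(self):
        rng = np.random.default_rng(0)
        n = 40
        lines = [f"CL{i}" for i in range(n)]
        x = np.array([0, 1] * (n // 2))
        y = pd.Series(-2.0 * x + rng.normal(0, 0.1, n), index=lines)
        fm = FeatureMatrix(pd.DataFrame({"F": x}, index=lines))
        coefs = ph.elastic_net_screen(y, fm)
        assert coefs["F"] < 0
        assert 1.0 <= abs(coefs["F"]) <= 2.0

    def test_null_features_all_zero(self):
        zeroed = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 40
            lines = [f"CL{i}" for i in range(n)]
            X = rng.integers(0, 2, size=(n, 5))
            y = pd.Series(rng.normal(size=n), index=lines)
            fm = FeatureMatrix(pd.DataFrame(X, columns=[f"F{j}" for j in range(5)], index=lines))
            coefs = ph.elastic_net_screen(y, fm, random_state=seed)
            zeroed += (coefs == 0).all()
        assert zeroed >= 18

    def test_duplicated_columns_fit_is_stable(self):
        rng = np.random.default_rng(1)
        n = 40
        lines = [f"CL{i}" for i in range(n)]
        x = rng.integers(0, 2, n)
        y = pd.Series(-1.5 * x + rng.normal(0, 0.1, n), index=lines)
        fm_ab = FeatureMatrix(pd.DataFrame({"A": x, "B": x}, index=lines))
        fm_ba = FeatureMatrix(pd.DataFrame({"B": x, "A": x}, index=lines))
        c1 = ph.elastic_net_screen(y, fm_ab)
        c2 = ph.elastic_net_screen(y, fm_ba)
        X = np.column_stack([x, x])
        fit1 = X @ c1[["A", "B"]].to_numpy()
        fit2 = X @ c2[["A", "B"]].to_numpy()
        np.testing.assert_allclose(fit1, fit2, atol=1e-6)

    def test_constant_response_warns_zero(self, caplog):
        lines = [f"CL{i}" for i in range(40)]
        y = pd.Series(1.0, index=lines)
        fm = FeatureMatrix(
            pd.DataFrame({"F": [0, 1] * 20}, index=lines)
        )
        with caplog.at_level("WARNING", logger="bandscape"):
            coefs = ph.elastic_net_screen(y, fm)
        assert (coefs == 0).all()


class TestScreens:
    def test_min_group_marks_untestable(self):
        lines = [f"CL{i}" for i in range(10)]
        y = np.arange(10.0)
        fm = FeatureMatrix(pd.DataFrame({"F": [1, 1] + [0] * 8}, index=lines))
        out = ph.interaction_screen(_response_table(y, lines), fm)
        assert out.loc[0, "untestable"]
        assert not out.loc[0, "passes"]

    def test_same_drug_in_two_screens_gives_two_records(self):
        lines = [f"CL{i}" for i in range(12)]
        rng = np.random.default_rng(2)
        x = np.array([1] * 6 + [0] * 6)
        rows = []
        for screen in ("S1", "S2"):
            y = -2.0 * x + rng.normal(0, 0.1, 12)
            rows.append(
                pd.DataFrame({"cell_line": lines, "drug": "venetoclax",
                              "screen_id": screen, "log10_ic50": y})
            )
        table = DrugResponseTable(pd.concat(rows, ignore_index=True))
        fm = FeatureMatrix(pd.DataFrame({"ANCHOR": x}, index=lines))
        out = ph.anchor_screen(table, fm, "ANCHOR")
        assert len(out) == 2
        assert set(out["screen_id"]) == {"S1", "S2"}
        assert (out["direction"] == "sensitivity").all()

    def test_negating_responses_swaps_direction(self):
        cfg = SimulationConfig(
            seed=5,
            drugs=DrugConfig(
                n_cell_lines=30, n_drugs=4, screens=("S1",), n_features=3,
                planted_effects=(("ANCHOR_LOSS", "D001", "S1", -2.0),),
            ),
        )
        table, fm, _ = simulate_drug_response(cfg, stage_rngs(5)["drugs"])
        out1 = ph.interaction_screen(table, fm).set_index(["feature", "drug"])
        neg = DrugResponseTable(table.records.assign(log10_ic50=-table.records["log10_ic50"]))
        out2 = ph.interaction_screen(neg, fm).set_index(["feature", "drug"])
        t1 = out1[~out1["untestable"]]
        t2 = out2.loc[t1.index]
        np.testing.assert_allclose(t2["mean_diff"], -t1["mean_diff"], atol=1e-12)
        np.testing.assert_allclose(t2["r_pb"], -t1["r_pb"], atol=1e-12)
        np.testing.assert_allclose(t2["mw_p"], t1["mw_p"], atol=1e-12)
        np.testing.assert_allclose(t2["q"], t1["q"], atol=1e-12)
        assert (
            t2["direction"].map({"sensitivity": "resistance", "resistance": "sensitivity"})
            == t1["direction"]
        ).all()

    def test_pdx_group_comparison(self):
        out = ph.pdx_group_comparison([0.2, 0.3, 0.25], [0.6, 0.7, 0.65])
        assert out["mean_diff"] < 0
        assert out["mw_p"] == pytest.approx(0.1)
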