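import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from bandscape import associations as assoc
from bandscape.datatypes import CohortTable
from bandscape.errors import DegenerateDataError, ValidationError


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Independent two-sided Fisher p: sum hypergeometric probabilities of
    all tables (same margins) no more likely than the observed one."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


class TestBinaryAnchor:
    def test_mixed_statuses(self):
        s = pd.Series(
            ["loss", "deep_loss", "neutral", "gain"], index=["S1", "S2", "S3", "S4"]
        )
        anchor, excluded = assoc.binary_anchor(s)
        assert anchor.to_dict() == {"S1": 1, "S2": 1, "S3": 0}
        assert excluded == ["S4"]

    def test_all_neutral_degenerate(self):
        s = pd.Series(["neutral"] * 4, index=list("abcd"))
        with pytest.raises(DegenerateDataError):
            assoc.binary_anchor(s)

    def test_ambiguous_only_degenerate(self):
        s = pd.Series(["ambiguous"] * 4, index=list("abcd"))
        with pytest.raises(DegenerateDataError):
            assoc.binary_anchor(s)


class TestFisher:
    def test_small_table_exact_p(self):
        r = assoc.fisher_from_counts(3, 0, 0, 3)
        assert r.p_value == pytest.approx(2 / 20)  # 2 of the C(6,3)=20 tables
        assert r.direction > 0
        assert r.call == "not_significant"  # p = 0.1 >= 0.05

    def test_balanced_table_is_null(self):
        r = assoc.fisher_from_counts(10, 10, 10, 10)
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.direction == 0.0
        assert r.score == 0.0

    def test_haldane_correction_on_zero_cell(self):
        r = assoc.fisher_from_counts(10, 0, 10, 10)
        assert r.odds_ratio == pytest.approx(21.0)  # (10.5*10.5)/(0.5*10.5)
        assert r.direction == pytest.approx(np.log2(21.0))

    def test_score_zero_at_p_one(self):
        r = assoc.fisher_from_counts(1, 0, 0, 0)
        assert r.p_value == pytest.approx(1.0)
        assert r.score == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            assoc.fisher_association(np.zeros(3), np.zeros(4))

    @settings(derandomize=True, max_examples=300)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_p_matches_enumeration(self, counts):
        a, b, c, d = counts
        if a + b + c + d == 0:
            return
        r = assoc.fisher_from_counts(a, b, c, d)
        assert r.p_value == pytest.approx(fisher_p_enumeration(a, b, c, d), rel=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(*[st.integers(1, 15)] * 4))
    def test_label_swap_flips_direction(self, counts):
        a, b, c, d = counts
        r1 = assoc.fisher_from_counts(a, b, c, d)
        r2 = assoc.fisher_from_counts(c, d, a, b)  # anchor labels 0<->1
        assert r2.p_value == pytest.approx(r1.p_value, rel=1e-12)
        assert r2.direction == pytest.approx(-r1.direction, rel=1e-12)
        assert r2.score == pytest.approx(-r1.score, rel=1e-9)


def _screen_inputs(n=100, seed=0):
    rng = np.random.default_rng(seed)
    idx = [f"S{i}" for i in range(n)]
    anchor = pd.Series(rng.integers(0, 2, n), index=idx)
    features = pd.DataFrame(
        {
            "rare": (rng.random(n) < 0.01).astype(int),
            "common": (rng.random(n) < 0.4).astype(int),
        },
        index=idx,
    )
    return anchor, features


class TestScreen:
    def test_low_prevalence_feature_not_tested(self):
        anchor, features = _screen_inputs()
        results = assoc.screen_features(anchor, features, min_prevalence=0.02)
        assert {r.feature_id for r in results} == {"common"}

    def test_empty_surviving_set_warns(self, caplog):
        anchor, features = _screen_inputs()
        with caplog.at_level("WARNING", logger="bandscape"):
            results = assoc.screen_features(anchor, features, min_prevalence=0.99)
        assert results == []
        assert any("prevalence" in r.message for r in caplog.records)

    def test_sorted_by_absolute_score(self):
        rng = np.random.default_rng(1)
        idx = [f"S{i}" for i in range(200)]
        anchor = pd.Series([1] * 100 + [0] * 100, index=idx)
        features = pd.DataFrame(
            {
                "strong": anchor.to_numpy(),
                "weak": rng.integers(0, 2, 200),
            },
            index=idx,
        )
        results = assoc.screen_features(anchor, features)
        assert [r.feature_id for r in results][0] == "strong"

    def test_adjacent_features_flagged_not_removed(self):
        anchor, features = _screen_inputs()
        results = assoc.screen_features(
            anchor, features, adjacent_features={"common"}
        )
        by_id = {r.feature_id: r for r in results}
        assert by_id["common"].flagged_adjacent


class TestConsistency:
    @staticmethod
    def _result(feature, call, score=1.0):
        return assoc.AssociationResult(feature, 1, 1, 1, 1, 1.0, 0.01, 1.0, score, call)

    def test_same_call_is_consistent(self):
        out = assoc.cross_cohort_consistency(
            [self._result("TP53", "co_occurring")], [self._result("TP53", "co_occurring")]
        )
        assert out["feature_id"].tolist() == ["TP53"]

    def test_call_mismatch_not_consistent(self):
        out = assoc.cross_cohort_consistency(
            [self._result("TP53", "co_occurring")],
            [self._result("TP53", "not_significant")],
        )
        assert out.empty

    def test_disjoint_namespaces_empty(self, caplog):
        with caplog.at_level("WARNING", logger="bandscape"):
            out = assoc.cross_cohort_consistency(
                [self._result("A", "co_occurring")], [self._result("B", "co_occurring")]
            )
        assert out.empty


class TestStratified:
    @staticmethod
    def _clinical(idx, subtypes):
        return CohortTable(
            pd.DataFrame(
                {
                    "sample_id": idx,
                    "pam50": subtypes,
                    "er": "ER+",
                    "her2": "HER2-",
                    "os_months": 1.0,
                    "os_event": 0,
                }
            )
        )

    def test_single_level_equals_unstratified(self):
        anchor, features = _screen_inputs()
        clinical = self._clinical(list(anchor.index), ["LumA"] * len(anchor))
        per_stratum, untestable = assoc.stratified_screen(anchor, features, clinical)
        flat = assoc.screen_features(anchor, features)
        assert untestable == []
        assert [(r.feature_id, r.p_value) for r in per_stratum["LumA"]] == [
            (r.feature_id, r.p_value) for r in flat
        ]

    def test_degenerate_stratum_reported_untestable(self):
        anchor, features = _screen_inputs()
        subtypes = ["LumA"] * len(anchor)
        # force one stratum where the anchor is all zero
        anchor = anchor.copy()
        subtypes[:10] = ["Basal"] * 10
        anchor.iloc[:10] = 0
        clinical = self._clinical(list(anchor.index), subtypes)
        _, untestable = assoc.stratified_screen(anchor, features, clinical)
        assert untestable == ["Basal"]

    def test_opposite_planted_effects_recovered_per_stratum(self):
        rng = np.random.default_rng(5)
        n = 400
        idx = [f"S{i}" for i in range(n)]
        subtypes = ["LumA"] * 200 + ["Basal"] * 200
        anchor = pd.Series(rng.integers(0, 2, n), index=idx)
        f = np.empty(n, dtype=int)
        a = anchor.to_numpy()
        # co-occurring in LumA, mutually exclusive in Basal
        f[:200] = np.where(a[:200] == 1, rng.random(200) < 0.7, rng.random(200) < 0.2)
        f[200:] = np.where(a[200:] == 1, rng.random(200) < 0.2, rng.random(200) < 0.7)
        features = pd.DataFrame({"flip": f}, index=idx)
        clinical = self._clinical(idx, subtypes)
        per_stratum, _ = assoc.stratified_screen(anchor, features, clinical)
        assert per_stratum["LumA"][0].call == "co_occurring"
        assert per_stratum["Basal"][0].call == "mutually_exclusive"
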