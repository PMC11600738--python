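import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bandscape import bands
from bandscape.datatypes import CohortTable, GeneCNMatrix, GenomeAnnotation
from bandscape.errors import DegenerateDataError, ValidationError

MISSING = float("nan")


def brute_force_call(values) -> str:
    """Independent re-statement of the call rule by explicit set logic."""
    observed = sorted({v for v in values if v == v})  # drop NaN
    if not observed:
        return "missing"
    if len(observed) > 1:
        return "ambiguous"
    return {-2: "deep_loss", -1: "loss", 0: "neutral", 1: "gain", 2: "amplification"}[
        observed[0]
    ]


class TestCallBandStatus:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([-1, -1, -1], "loss"),
            ([-1, 0, -1], "ambiguous"),
            ([2, 2, MISSING], "amplification"),
            ([MISSING, MISSING], "missing"),
            ([0], "neutral"),
            ([-2, -2], "deep_loss"),
            ([1, 1, 1, 1], "gain"),
        ],
    )
    def test_examples(self, values, expected):
        assert bands.call_band_status(values) == expected

    def test_out_of_range_value_errors(self):
        with pytest.raises(ValidationError):
            bands.call_band_status([3])

    def test_matches_oracle_on_short_vectors(self):
        symbols = [-2, -1, 0, 1, 2, MISSING]
        for length in (1, 2, 3):
            for combo in itertools.product(symbols, repeat=length):
                assert bands.call_band_status(list(combo)) == brute_force_call(combo)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.sampled_from([-2.0, -1.0, 0.0, 1.0, 2.0, MISSING]), min_size=1, max_size=6
        )
    )
    def test_permutation_invariance(self, values):
        base = bands.call_band_status(values)
        assert bands.call_band_status(values[::-1]) == base


class TestAssignment:
    def test_midpoint_on_boundary_goes_to_right_band(self):
        annotation = GenomeAnnotation(
            genes=pd.DataFrame(
                [("G", "chr1", 100, 200)], columns=["gene_id", "chrom", "start", "end"]
            ),
            bands=pd.DataFrame(
                [("chr1", 0, 150, "1p1", "gneg"), ("chr1", 150, 300, "1q1", "gneg")],
                columns=["chrom", "start", "end", "band_name", "stain"],
            ),
        )
        mapping, unassigned = bands.assign_genes_to_bands(annotation)
        assert mapping == {"1q1": ["G"]}
        assert unassigned == []

    def test_gene_inside_band(self, tiny_annotation):
        mapping, _ = bands.assign_genes_to_bands(tiny_annotation)
        assert "RB1" in mapping["13q14.2"]

    def test_gene_without_bands_reported(self, tiny_annotation):
        genes = pd.concat(
            [
                tiny_annotation.genes,
                pd.DataFrame(
                    [("MT1", "chrM", 0, 100)], columns=["gene_id", "chrom", "start", "end"]
                ),
            ],
            ignore_index=True,
        )
        annotation = GenomeAnnotation(genes=genes, bands=tiny_annotation.bands)
        _, unassigned = bands.assign_genes_to_bands(annotation)
        assert unassigned == ["MT1"]


class TestLossFrequencies:
    def test_counting(self):
        statuses = ["loss"] * 3 + ["neutral"] * 7
        table = pd.DataFrame([statuses], index=["13q14.2"], columns=[f"S{i}" for i in range(10)])
        out = bands.band_loss_frequencies(table)
        assert out.loc["13q14.2", "frequency"] == pytest.approx(0.30)

    def test_ambiguous_counts_in_denominator_only(self):
        table = pd.DataFrame(
            [["ambiguous"] * 4], index=["1p1"], columns=[f"S{i}" for i in range(4)]
        )
        out = bands.band_loss_frequencies(table)
        assert out.loc["1p1", "frequency"] == 0.0
        assert out.loc["1p1", "n_callable"] == 4

    def test_tie_broken_by_genomic_order(self):
        table = pd.DataFrame(
            [["loss", "neutral"], ["neutral", "loss"]],
            index=["1p1", "1q1"],
            columns=["S1", "S2"],
        )
        out = bands.band_loss_frequencies(table)
        assert out.loc["1p1", "rank"] == 1
        assert out.loc["1q1", "rank"] == 2

    def test_empty_table_errors(self):
        with pytest.raises(DegenerateDataError):
            bands.band_loss_frequencies(pd.DataFrame())


def _cn_with_frequencies(tiny_annotation, in_band_loss, out_band_loss, n=100, seed=0):
    """CN matrix where 13q14.2 genes are lost in a given fraction of samples."""
    rng = np.random.default_rng(seed)
    genes = list(tiny_annotation.genes["gene_id"])
    samples = [f"S{i}" for i in range(n)]
    vals = np.zeros((len(genes), n))
    for i, g in enumerate(genes):
        frac = in_band_loss if g in ("RB1", "C2") else out_band_loss
        k = int(round(frac * n)) + rng.integers(-2, 3)
        k = int(np.clip(k, 0, n))
        vals[i, :k] = -1
    return GeneCNMatrix(pd.DataFrame(vals, index=genes, columns=samples))


class TestBandVsGenome:
    def test_elevated_in_band_loss_gives_positive_t(self, tiny_annotation):
        cn = _cn_with_frequencies(tiny_annotation, 0.40, 0.20)
        res = bands.compare_band_vs_genome(cn, tiny_annotation, "13q14.2", mode="loss")
        assert res["t"] > 0
        assert res["p"] < 0.01
        assert res["mean_in"] > res["mean_out"]

    def test_identical_frequency_groups(self, tiny_annotation):
        # in-band and out-of-band genes share the same frequency profile
        # {0.1, 0.3}, so the contrast is exactly null
        genes = list(tiny_annotation.genes["gene_id"])
        n = 10
        vals = np.zeros((len(genes), n))
        for i in range(len(genes)):
            vals[i, : (1 if i % 2 == 0 else 3)] = -1
        cn = GeneCNMatrix(
            pd.DataFrame(vals, index=genes, columns=[f"S{i}" for i in range(n)])
        )
        res = bands.compare_band_vs_genome(cn, tiny_annotation, "13q14.2", mode="loss")
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_single_in_band_gene_errors(self, tiny_annotation):
        cn = _cn_with_frequencies(tiny_annotation, 0.4, 0.2)
        cn2 = GeneCNMatrix(cn.values.drop(index="C2"))
        with pytest.raises(DegenerateDataError):
            bands.compare_band_vs_genome(cn2, tiny_annotation, "13q14.2")

    def test_constant_frequencies_error(self, tiny_annotation):
        genes = list(tiny_annotation.genes["gene_id"])
        vals = np.zeros((len(genes), 10))
        cn = GeneCNMatrix(
            pd.DataFrame(vals, index=genes, columns=[f"S{i}" for i in range(10)])
        )
        with pytest.raises(DegenerateDataError):
            bands.compare_band_vs_genome(cn, tiny_annotation, "13q14.2")


class TestSubtypeContingency:
    @staticmethod
    def _clinical(subtypes):
        return CohortTable(
            pd.DataFrame(
                {
                    "sample_id": [f"S{i}" for i in range(len(subtypes))],
                    "pam50": subtypes,
                    "er": "ER+",
                    "her2": "HER2-",
                    "os_months": 1.0,
                    "os_event": 0,
                }
            )
        )

    def test_two_by_two_chi_square_value(self):
        # contingency [[20,10],[10,20]]: chi2 = n(ad-bc)^2/(r1 r2 c1 c2) = 6.67
        statuses = pd.Series(
            ["loss"] * 30 + ["neutral"] * 30, index=[f"S{i}" for i in range(60)]
        )
        subtypes = ["LumA"] * 20 + ["Basal"] * 10 + ["LumA"] * 10 + ["Basal"] * 20
        res = bands.subtype_status_table(statuses, self._clinical(subtypes))
        assert res["chi2"] == pytest.approx(6.67, abs=0.005)
        assert res["p"] == pytest.approx(0.0098, abs=0.0002)

    def test_equal_rows_give_zero(self):
        statuses = pd.Series(
            ["loss"] * 20 + ["neutral"] * 20, index=[f"S{i}" for i in range(40)]
        )
        subtypes = (["LumA"] * 10 + ["Basal"] * 10) * 2
        res = bands.subtype_status_table(statuses, self._clinical(subtypes))
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_low_expected_count_flagged_not_fatal(self):
        statuses = pd.Series(
            ["loss"] * 3 + ["neutral"] * 37, index=[f"S{i}" for i in range(40)]
        )
        subtypes = ["LumA"] * 20 + ["Basal"] * 20
        res = bands.subtype_status_table(statuses, self._clinical(subtypes))
        assert res["low_expected"] is True
        assert np.isfinite(res["chi2"])

    def test_single_subtype_errors(self):
        statuses = pd.Series(["loss", "neutral"], index=["S0", "S1"])
        with pytest.raises(DegenerateDataError):
            bands.subtype_status_table(statuses, self._clinical(["LumA", "LumA"]))
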