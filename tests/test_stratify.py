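"""Four-way TF classification, dot-plot statistics, group tests, the
detected-genes diagnostic, and the intensity analogue."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import isletstrat as ist
from isletstrat.genes import TF_GROUPS
from isletstrat.stratify import (
    TFPair,
    binarize_and_classify,
    classify_combinatorial,
    classify_intensity,
    compare_groups,
    detected_genes_by_level,
    dotplot_stats,
)

from conftest import cell_table_for, make_norm


class TestClassification:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (0.7, 0.4, "A-only"),
            (0.0, 0.0, "None"),
            (0.4, 0.7, "B-only"),
            (0.7, 0.7, "Both"),
            (0.5, 0.5, "None"),  # exactly at threshold counts as low
            (0.5, 0.6, "B-only"),
        ],
    )
    def test_threshold_rules(self, a, b, expected):
        out = classify_combinatorial(
            np.array([a]), np.array([b]), threshold=0.5
        )
        assert out[0] == expected

    def test_nonzero_detection_mode(self):
        out = classify_combinatorial(
            np.array([0.1, 0.0]), np.array([0.0, 0.2]),
            threshold=0.5, detection="nonzero",
        )
        assert list(out) == ["A-only", "B-only"]

    def test_pair_validation(self):
        with pytest.raises(ValueError):
            TFPair("ARX", "ARX", cell_type="alpha")
        with pytest.raises(ValueError):
            TFPair("ARX", "MAFB", cell_type="alpha", threshold=-1.0)

    def test_partition_and_donor_fractions(self):
        norm = make_norm(
            [[2.0, 2.0], [2.0, 0.0], [0.0, 2.0], [0.0, 0.0], [2.0, 2.0]],
            ["ARX", "MAFB"],
        )
        table = cell_table_for(
            norm, "alpha", donors=["d1", "d1", "d2", "d2", "d2"]
        )
        res = binarize_and_classify(
            norm, table, TFPair("ARX", "MAFB", cell_type="alpha")
        )
        assert res.n_cells == 5
        assert res.pooled_fractions.sum() == pytest.approx(1.0)
        counts = res.labels.value_counts()
        assert counts.sum() == 5  # labels partition the cells
        assert np.allclose(res.per_donor_fractions.sum(axis=1), 1.0)
        assert res.per_donor_fractions.loc["d1", "Both"] == pytest.approx(0.5)

    def test_missing_tf_gene_rejected(self):
        norm = make_norm([[1.0]], ["ARX"])
        table = cell_table_for(norm, "alpha")
        with pytest.raises(ValueError):
            binarize_and_classify(
                norm, table, TFPair("ARX", "MAFB", cell_type="alpha")
            )

    @given(st.floats(0.0, 3.0), st.floats(0.0, 3.0))
    @settings(max_examples=100, derandomize=True)
    def test_threshold_monotonicity(self, t_low, t_high):
        """Raising the threshold never increases the Both fraction."""
        t_low, t_high = sorted((t_low, t_high))
        rng = np.random.default_rng(5)
        a = rng.exponential(1.0, 200)
        b = rng.exponential(1.0, 200)
        both_low = (classify_combinatorial(a, b, t_low) == "Both").mean()
        both_high = (classify_combinatorial(a, b, t_high) == "Both").mean()
        assert both_high <= both_low


class TestDotplotStats:
    def _fixture(self):
        # 4 groups x 2 cells; gene X group means 1,2,3,4; gene FLAT all 2;
        # gene ZERO undetected everywhere
        values = np.array(
            [
                [1.0, 2.0, 0.0],
                [1.0, 2.0, 0.0],
                [2.0, 2.0, 0.0],
                [2.0, 2.0, 0.0],
                [3.0, 2.0, 0.0],
                [3.0, 2.0, 0.0],
                [4.0, 2.0, 0.0],
                [4.0, 2.0, 0.0],
            ]
        )
        norm = make_norm(values, ["X", "FLAT", "ZERO"])
        table = cell_table_for(norm, "alpha")
        labels = pd.Series(
            np.repeat(TF_GROUPS, 2), index=norm.barcodes, name="tf_group"
        )
        from isletstrat.stratify import TFGroupResult

        res = TFGroupResult(
            pair=TFPair("ARX", "MAFB", cell_type="alpha"),
            labels=labels,
            pooled_fractions=labels.value_counts(normalize=True),
            per_donor_fractions=pd.DataFrame(),
            n_cells=8,
        )
        return norm, res

    def test_zscores_sample_sd(self):
        norm, res = self._fixture()
        out = dotplot_stats(norm, res, ["X"])
        z = out.set_index("group")["z_score"]
        expected = {
            "None": -1.1619, "A-only": -0.3873,
            "B-only": 0.3873, "Both": 1.1619,
        }
        for g, e in expected.items():
            assert z[g] == pytest.approx(e, abs=1e-4)

    def test_flat_gene_zero_z(self):
        norm, res = self._fixture()
        out = dotplot_stats(norm, res, ["FLAT"])
        assert (out["z_score"] == 0).all()
        assert not out["undetected"].any()

    def test_undetected_gene_flagged(self):
        norm, res = self._fixture()
        out = dotplot_stats(norm, res, ["ZERO"])
        assert (out["pct_detected"] == 0).all()
        assert (out["z_score"] == 0).all()
        assert out["undetected"].all()

    def test_pct_detected_counts_nonzero(self):
        norm, res = self._fixture()
        out = dotplot_stats(norm, res, ["X"])
        assert (out["pct_detected"] == 1.0).all()


class TestCompareGroups:
    def _result(self, norm):
        table = cell_table_for(norm, "alpha")
        return binarize_and_classify(
            norm, table, TFPair("ARX", "MAFB", cell_type="alpha")
        )

    def test_identical_groups_p_one(self):
        rng = np.random.default_rng(0)
        n = 40
        arx = np.r_[np.full(n, 2.0), np.zeros(n)]
        mafb = np.full(2 * n, 2.0)
        gene = np.full(2 * n, 1.5)
        norm = make_norm(
            np.c_[arx, mafb, gene], ["ARX", "MAFB", "G1"]
        )
        res = self._result(norm)
        out = compare_groups(norm, res, ["G1"])
        assert (out["p_value"] == 1.0).all()

    def test_shifted_gene_significant_and_bh_family(self):
        rng = np.random.default_rng(1)
        n = 60
        arx = np.r_[np.full(n, 2.0), np.zeros(n)]
        mafb = np.full(2 * n, 2.0)
        up = np.r_[rng.normal(3.0, 0.3, n), rng.normal(1.0, 0.3, n)]
        flat = rng.normal(1.0, 0.3, 2 * n)
        norm = make_norm(
            np.abs(np.c_[arx, mafb, up, flat]), ["ARX", "MAFB", "UP", "FLAT"]
        )
        res = self._result(norm)
        out = compare_groups(norm, res, ["UP", "FLAT"])
        assert set(out["comparison"]) == {"Both_vs_B-only"}
        up_p = out.loc[out["gene"] == "UP", "p_adjusted"].iloc[0]
        flat_p = out.loc[out["gene"] == "FLAT", "p_adjusted"].iloc[0]
        assert up_p < 0.05 < flat_p
        assert (out["p_adjusted"] >= out["p_value"] - 1e-12).all()

    def test_all_pairs_scheme(self):
        rng = np.random.default_rng(2)
        arx = rng.choice([0.0, 2.0], 80)
        mafb = rng.choice([0.0, 2.0], 80)
        gene = rng.normal(1.0, 0.2, 80)
        norm = make_norm(np.abs(np.c_[arx, mafb, gene]), ["ARX", "MAFB", "G"])
        res = self._result(norm)
        out = compare_groups(norm, res, ["G"], scheme="all_pairs")
        assert len(out) == 6  # C(4,2) comparisons


class TestDetectedGenesByLevel:
    def test_uniform_coverage(self):
        # every cell detects 3 genes incl. the TF; both strata report
        # frac > 1000 of 0 and identical medians
        values = np.tile([2.0, 1.0, 1.0], (10, 1))
        values[5:, 0] = 0.2  # TF-low cells
        norm = make_norm(values, ["MAFA", "G1", "G2"])
        out = detected_genes_by_level(norm, "MAFA", 0.5)
        assert set(out.index) == {"low", "high"}
        assert out.loc["low", "median"] == out.loc["high", "median"]
        assert (out["frac_gt_1000"] == 0.0).all()

    def test_empty_stratum_absent(self):
        values = np.tile([2.0, 1.0], (5, 1))
        norm = make_norm(values, ["MAFA", "G1"])
        out = detected_genes_by_level(norm, "MAFA", 0.5)
        assert list(out.index) == ["high"]

    def test_library_independent_of_tf_state(self, clean_alpha_sim):
        """Median detected genes differs < 10% between TF-low and TF-high
        cells when library size is independent of TF state."""
        _, counts, _ = clean_alpha_sim
        norm = ist.normalize_log(counts)
        out = detected_genes_by_level(norm, "MAFB", 0.5)
        lo, hi = out.loc["low", "median"], out.loc["high", "median"]
        assert abs(hi - lo) / max(hi, lo) < 0.10


class TestClassifyIntensity:
    def test_quadrants(self):
        table = pd.DataFrame(
            {
                "donor": ["d1"] * 4,
                "marker_a": [10.0, 2.0, 10.0, 2.0],
                "marker_b": [2.0, 2.0, 10.0, 10.0],
            }
        )
        res = classify_intensity(table, thresholds=(5.0, 5.0))
        assert list(res.labels) == ["hi/lo", "lo/lo", "hi/hi", "lo/hi"]

    def test_all_below_is_all_lolo(self):
        table = pd.DataFrame(
            {"donor": ["d1"] * 3, "marker_a": [1.0] * 3, "marker_b": [2.0] * 3}
        )
        res = classify_intensity(table, thresholds=(5.0, 5.0))
        assert res.pooled_fractions["lo/lo"] == 1.0

    def test_missing_values_excluded(self):
        table = pd.DataFrame(
            {
                "donor": ["d1", "d1", "d2"],
                "marker_a": [10.0, np.nan, 1.0],
                "marker_b": [10.0, 1.0, 1.0],
            }
        )
        res = classify_intensity(table, thresholds=(5.0, 5.0))
        assert res.n_excluded == 1
        assert res.n_cells == 2
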