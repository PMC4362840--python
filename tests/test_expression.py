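"""Unit and property tests for normalization, per-gene ANOVA, signed fold
changes, and the DE significance filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import diffpath as dp
from diffpath.expression import signed_to_log2


def _matrix(values, design, genes=None):
    values = np.atleast_2d(np.asarray(values, float))
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    return dp.ExpressionMatrix(genes, values, design)


class TestExpressionMatrix:
    def test_gene_symbols_uppercased(self, two_group_design):
        m = _matrix(np.zeros((2, 6)), two_group_design, genes=["acaa1", "Hsd17b4"])
        assert m.gene_ids == ["ACAA1", "HSD17B4"]

    def test_duplicate_symbols_after_uppercasing_rejected(self, two_group_design):
        with pytest.raises(ValueError, match="duplicate"):
            _matrix(np.zeros((2, 6)), two_group_design, genes=["acaa1", "ACAA1"])

    def test_non_finite_values_rejected(self, two_group_design):
        vals = np.zeros((1, 6))
        vals[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            _matrix(vals, two_group_design)

    def test_shape_mismatch_rejected(self, two_group_design):
        with pytest.raises(ValueError):
            _matrix(np.zeros((1, 5)), two_group_design)


class TestSampleDesign:
    def test_singleton_level_rejected(self):
        with pytest.raises(ValueError, match=">= 2 samples"):
            dp.SampleDesign(("a", "b", "c"), ("WT", "WT", "MKR"))

    def test_partial_factor_b_rejected(self):
        with pytest.raises(ValueError):
            dp.SampleDesign(("a", "b", "c", "d"), ("x",) * 4, ("u", "v"))

    def test_level_order_is_first_appearance(self, two_group_design):
        assert two_group_design.levels_a == ["WT", "MKR"]


class TestQuantileNormalize:
    def test_two_column_rank_mean_example(self):
        # sorted-position means: (1+4)/2, (2+5)/2, (3+6)/2
        design = dp.SampleDesign(("s1", "s2"), ("a", "a"))
        m = _matrix(np.array([[1, 4], [2, 5], [3, 6]]).T.T, design, genes=["X", "Y", "Z"])
        out = dp.quantile_normalize(m)
        np.testing.assert_allclose(out.values, [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_identical_columns_unchanged(self):
        design = dp.SampleDesign(("s1", "s2"), ("a", "a"))
        vals = np.array([[5.0, 5.0], [1.0, 1.0], [3.0, 3.0]])
        out = dp.quantile_normalize(_matrix(vals, design))
        np.testing.assert_allclose(out.values, vals)

    def test_order_preserved_within_columns(self, rng, two_group_design):
        vals = rng.normal(size=(30, 6))
        out = dp.quantile_normalize(_matrix(vals, two_group_design))
        for j in range(6):
            assert np.array_equal(np.argsort(vals[:, j]), np.argsort(out.values[:, j]))

    @given(st.integers(0, 2**31 - 1))
    def test_columns_share_multiset_and_idempotent(self, seed):
        # continuous draws: ties have probability zero
        rng = np.random.default_rng(seed)
        design = dp.SampleDesign(
            tuple(f"s{i}" for i in range(4)), ("a", "a", "b", "b")
        )
        m = _matrix(rng.normal(size=(12, 4)), design)
        once = dp.quantile_normalize(m)
        sorted_cols = np.sort(once.values, axis=0)
        for j in range(1, 4):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])
        twice = dp.quantile_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)


class TestTwoWayAnova:
    def test_hand_computed_2x2_sums_of_squares(self, crossed_design):
        # textbook decomposition for (1,2 | 3,4 // 5,6 | 9,10):
        # SS_A=50, SS_B=18, SS_AB=2, SS_within=2 (df 1,1,1,4) -> F = 100, 36, 4
        m = _matrix([[1, 2, 3, 4, 5, 6, 9, 10]], crossed_design)
        stat = dp.two_way_anova_per_gene(m)[0]
        assert stat.p_value_a == pytest.approx(sps.f.sf(100.0, 1, 4), rel=1e-12)
        assert stat.p_value_b == pytest.approx(sps.f.sf(36.0, 1, 4), rel=1e-12)
        assert stat.p_value_interaction == pytest.approx(sps.f.sf(4.0, 1, 4), rel=1e-12)
        assert stat.log2fc == pytest.approx(5.0)

    def test_matches_statsmodels_on_random_balanced_data(self, rng, crossed_design):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        vals = rng.normal(size=(5, 8))
        stats = dp.two_way_anova_per_gene(_matrix(vals, crossed_design))
        for i, stat in enumerate(stats):
            df = pd.DataFrame(
                {"y": vals[i], "a": crossed_design.factor_a, "b": crossed_design.factor_b}
            )
            tab = anova_lm(smf.ols("y ~ C(a) * C(b)", df).fit(), typ=2)
            assert stat.p_value_a == pytest.approx(tab.loc["C(a)", "PR(>F)"], rel=1e-8)
            assert stat.p_value_b == pytest.approx(tab.loc["C(b)", "PR(>F)"], rel=1e-8)
            assert stat.p_value_interaction == pytest.approx(
                tab.loc["C(a):C(b)", "PR(>F)"], rel=1e-8
            )

    def test_unbalanced_design_uses_type_ii(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        # unequal cell sizes (3,2,2,2)
        fa = ("A1",) * 5 + ("A2",) * 4
        fb = ("B1", "B1", "B1", "B2", "B2", "B1", "B1", "B2", "B2")
        design = dp.SampleDesign(tuple(f"s{i}" for i in range(9)), fa, fb)
        vals = rng.normal(size=(3, 9))
        stats = dp.two_way_anova_per_gene(_matrix(vals, design))
        for i, stat in enumerate(stats):
            df = pd.DataFrame({"y": vals[i], "a": fa, "b": fb})
            tab = anova_lm(smf.ols("y ~ C(a) + C(b) + C(a):C(b)", df).fit(), typ=2)
            assert stat.p_value_a == pytest.approx(tab.loc["C(a)", "PR(>F)"], rel=1e-6)

    def test_one_way_fallback_matches_f_oneway(self, rng, two_group_design):
        vals = rng.normal(size=(10, 6))
        stats = dp.two_way_anova_per_gene(_matrix(vals, two_group_design))
        for i, stat in enumerate(stats):
            expected = sps.f_oneway(vals[i, :3], vals[i, 3:]).pvalue
            assert stat.p_value_a == pytest.approx(expected, rel=1e-9)

    def test_zero_variance_gene_is_degenerate(self, two_group_design):
        m = _matrix([[2.5] * 6], two_group_design)
        stat = dp.two_way_anova_per_gene(m)[0]
        assert stat.degenerate
        assert np.isnan(stat.p_value_a)

    def test_null_pvalues_uniform_by_ks(self):
        rng = np.random.default_rng(7)
        design = dp.SampleDesign(
            tuple(f"s{i}" for i in range(6)), ("WT",) * 3 + ("MKR",) * 3
        )
        vals = rng.normal(size=(1500, 6))
        pvals = [s.p_value_a for s in dp.two_way_anova_per_gene(_matrix(vals, design))]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_contrast_direction(self, two_group_design):
        vals = np.array([[0.0, 0.0, 0.0, 1.0, 1.0, 1.0]])
        stat = dp.two_way_anova_per_gene(
            _matrix(vals, two_group_design), contrast=("WT", "MKR")
        )[0]
        assert stat.log2fc == pytest.approx(1.0)
        flipped = dp.two_way_anova_per_gene(
            _matrix(vals, two_group_design), contrast=("MKR", "WT")
        )[0]
        assert flipped.log2fc == pytest.approx(-1.0)


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "d, expected",
        [
            (1.0, 2.0),
            (0.0, 1.0),
            (np.log2(1 / 2.2625), -2.2625),  # down-regulated ACAA1-style value
            (-1.0, -2.0),
        ],
    )
    def test_known_values(self, d, expected):
        assert dp.signed_fold_change(0.0, d) == pytest.approx(expected, rel=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            dp.signed_fold_change(0.0, np.inf)

    @given(st.floats(-20, 20))
    def test_magnitude_never_below_one(self, d):
        assert abs(dp.signed_fold_change(0.0, d)) >= 1.0

    @given(
        st.floats(1.0, 1e6).flatmap(
            lambda mag: st.sampled_from([mag, -mag])
        )
    )
    def test_round_trip_through_log2(self, fc):
        assert dp.signed_fold_change(0.0, signed_to_log2(fc)) == pytest.approx(
            fc, rel=1e-9
        )

    def test_inverse_rejects_magnitude_below_one(self):
        with pytest.raises(ValueError):
            signed_to_log2(0.5)


def _stat(gene, p, fc):
    return dp.GeneStat(gene_id=gene, p_value_a=p, log2fc=signed_to_log2(fc), signed_fc=fc)


class TestDEFilter:
    def test_paper_style_gene_retained(self):
        table = dp.apply_de_filter([_stat("ACSL4", 0.02, 3.1309)])
        assert table.records == {"ACSL4": 3.1309}

    def test_boundary_fold_change_excluded_under_strict(self):
        table = dp.apply_de_filter([_stat("G1", 0.001, 1.5)])
        assert "G1" not in table.records
        loose = dp.apply_de_filter(
            [_stat("G1", 0.001, 1.5)], dp.FilterCriteria(strict=False)
        )
        assert "G1" in loose.records

    def test_failing_p_excluded(self):
        table = dp.apply_de_filter([_stat("G1", 0.06, -4.0)])
        assert "G1" not in table.records

    def test_degenerate_gene_never_retained(self):
        stat = dp.GeneStat("G1", np.nan, 2.0, 4.0, degenerate=True)
        assert dp.apply_de_filter([stat]).records == {}

    def test_empty_stats_warns_and_returns_empty(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="diffpath.expression"):
            table = dp.apply_de_filter([])
        assert table.records == {} and table.universe == ()
        assert any("empty" in r.message for r in caplog.records)

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            dp.FilterCriteria(p_cutoff=0.0)
        with pytest.raises(ValueError):
            dp.FilterCriteria(fc_cutoff=0.9)

    @given(
        st.lists(
            st.tuples(
                st.floats(0.001, 0.999),
                st.floats(1.0, 10.0),
                st.booleans(),
            ),
            max_size=30,
        ),
        st.floats(0.01, 0.2),
        st.floats(1.1, 3.0),
    )
    def test_tightening_thresholds_is_monotone(self, rows, p_cut, fc_cut):
        stats = [
            _stat(f"G{i}", p, mag if up else -mag)
            for i, (p, mag, up) in enumerate(rows)
        ]
        base = dp.apply_de_filter(stats, dp.FilterCriteria(p_cut, fc_cut))
        tighter = dp.apply_de_filter(
            stats, dp.FilterCriteria(p_cut / 2, fc_cut + 0.5)
        )
        assert tighter.genes <= base.genes


class TestExportGeneTable:
    def test_one_row_per_universe_gene(self):
        table = dp.DEGeneTable("c", ("A", "B", "C"), {"B": -2.0})
        frame = dp.export_gene_table(table)
        assert len(frame) == 3
        assert frame["signed_fc"].isna().sum() == 2

    def test_empty_table_all_na(self):
        frame = dp.export_gene_table(dp.DEGeneTable("c", ("A", "B"), {}))
        assert frame["signed_fc"].isna().all()

    def test_gene_outside_universe_rejected(self):
        table = dp.DEGeneTable("c", ("A", "B"), {"B": 2.0})
        with pytest.raises(ValueError):
            dp.export_gene_table(table, universe=["A"])
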