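"""ANOVA associations, FDR, expression binarization and emergent flagging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from comboscreen.biomarkers import (
    SignificanceThresholds,
    anova_association,
    binarize_expression,
    build_subgroups,
    flag_emergent,
    run_anova_suite,
)


def brute_force_bh(pvals):
    """Independent step-up Benjamini–Hochberg implementation."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestBinarizeExpression:
    def test_standard_normal_tail_fraction(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame({"G1": rng.normal(0, 1, 5000)})
        feats = binarize_expression(expr)
        # ~2.3% beyond Z=2 in either tail
        assert feats["G1_up"].mean() == pytest.approx(0.023, abs=0.01)
        assert feats["G1_down"].mean() == pytest.approx(0.023, abs=0.01)

    def test_constant_gene_yields_no_flags(self):
        expr = pd.DataFrame({"G1": np.full(50, 3.0)})
        feats = binarize_expression(expr)
        assert feats["G1_up"].sum() == 0 and feats["G1_down"].sum() == 0

    def test_z_scores_are_within_panel(self):
        """A line extreme inside a basket need not be extreme pan-cancer."""
        rng = np.random.default_rng(1)
        pan = pd.DataFrame({"G1": np.concatenate([rng.normal(0, 1, 180),
                                                  rng.normal(6, 1, 20)])})
        basket = pan.iloc[180:]
        pan_feats = binarize_expression(pan)
        basket_feats = binarize_expression(basket)
        shifted = pan.index[180:]
        assert pan_feats.loc[shifted, "G1_up"].sum() > 10
        assert basket_feats["G1_up"].sum() <= 2


class TestAnovaAssociation:
    def test_identical_groups_non_significant(self):
        y = np.concatenate([np.full(10, 0.4), np.full(10, 0.4)])
        f = np.repeat([1, 0], 10)
        res = anova_association(y, f)
        assert res["glass_delta_pos"] == 0 and res["glass_delta_neg"] == 0
        assert res["p_value"] == pytest.approx(1.0)

    def test_f_equals_squared_t_statistic(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(12, 60))
            f = rng.binomial(1, 0.4, n)
            if min(f.sum(), n - f.sum()) < 3:
                continue
            y = rng.normal(0, 1, n) + 0.5 * f
            res = anova_association(y, f)
            t, p = stats.ttest_ind(y[f == 1], y[f == 0], equal_var=True)
            assert res["f_stat"] == pytest.approx(t**2, rel=1e-9)
            assert res["p_value"] == pytest.approx(p, rel=1e-9)

    def test_planted_three_sd_effect_is_recovered(self):
        # effect of 3 noise-SDs, 200 lines, prevalence 0.3
        rng = np.random.default_rng(3)
        f = (np.arange(200) < 60).astype(int)
        y = rng.normal(0.3, 0.05, 200) + 0.15 * f
        res = anova_association(y, f)
        assert res["p_value"] < 1e-6
        assert res["glass_delta_pos"] >= 1 and res["glass_delta_neg"] >= 1

    def test_small_group_skipped(self):
        y = np.arange(10.0)
        f = np.array([1, 1] + [0] * 8)
        res = anova_association(y, f, min_group_size=3)
        assert res["skipped"] is not None
        assert np.isnan(res["p_value"])

    def test_covariate_adjustment_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 120
        tissue = rng.integers(0, 4, n)
        f = rng.binomial(1, 0.3, n)
        y = 0.2 * tissue + 0.3 * f + rng.normal(0, 0.5, n)
        dummies = pd.get_dummies(tissue, drop_first=True).to_numpy(float)
        res = anova_association(y, f, covariates=dummies)
        X = sm.add_constant(np.column_stack([dummies, f]))
        fit = sm.OLS(y, X).fit()
        assert res["p_value"] == pytest.approx(fit.pvalues[-1], rel=1e-8)
        assert res["f_stat"] == pytest.approx(fit.tvalues[-1] ** 2, rel=1e-8)

    def test_glass_deltas_shift_and_scale_behavior(self):
        rng = np.random.default_rng(5)
        f = rng.binomial(1, 0.5, 80)
        y = rng.normal(0, 1, 80) + f
        base = anova_association(y, f)
        shifted = anova_association(y + 10.0, f)
        scaled = anova_association(3.0 * y, f)
        for key in ("glass_delta_pos", "glass_delta_neg"):
            assert shifted[key] == pytest.approx(base[key])
            assert scaled[key] == pytest.approx(base[key])


class TestFdrFamilies:
    def test_bh_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            p = rng.uniform(0, 1, int(rng.integers(3, 40)))
            _, fdr, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(fdr, brute_force_bh(p), atol=1e-12)

    def test_suite_fdr_computed_within_subgroup_metric_family(self, small_screen,
                                                              small_pipeline_tables):
        from comboscreen.pipeline import biomarker_input

        tables = small_pipeline_tables
        assoc = run_anova_suite(
            biomarker_input(tables["response"], tables["synergy"]),
            small_screen.features,
            annotations=small_screen.annotations,
        )
        for (_, _), grp in assoc.groupby(["subgroup", "metric"]):
            mask = grp["p_value"].notna()
            if mask.sum() == 0:
                continue
            np.testing.assert_allclose(
                grp.loc[mask, "fdr"].to_numpy(),
                brute_force_bh(grp.loc[mask, "p_value"].to_numpy()),
                atol=1e-12,
            )


def assoc_row(feature, combo, subgroup, metric, significant):
    return {
        "feature": feature, "combo_id": combo, "subgroup": subgroup,
        "metric": metric, "significant": significant,
    }


class TestFlagEmergent:
    def _table(self, rows):
        base = []
        for feature, combo, subgroup in {(r["feature"], r["combo_id"], r["subgroup"])
                                         for r in rows}:
            for metric in ("emax_a", "emax_b", "combo_emax", "bliss_matrix",
                           "bliss_window"):
                base.append(assoc_row(feature, combo, subgroup, metric, False))
        df = pd.DataFrame(base)
        for r in rows:
            mask = (
                (df["feature"] == r["feature"]) & (df["combo_id"] == r["combo_id"])
                & (df["subgroup"] == r["subgroup"]) & (df["metric"] == r["metric"])
            )
            df.loc[mask, "significant"] = r["significant"]
        return df

    def test_combination_only_association_is_emergent(self):
        df = self._table([assoc_row("F1", "c1", "pan", "bliss_matrix", True)])
        out, partition = flag_emergent(df)
        assert out[out["metric"] == "bliss_matrix"]["emergent"].all()
        assert partition == {"bliss_only": 1, "both": 0, "combo_emax_only": 0,
                             "total": 1}

    def test_single_agent_significance_blocks_emergence(self):
        df = self._table(
            [
                assoc_row("F1", "c1", "pan", "bliss_matrix", True),
                assoc_row("F1", "c1", "pan", "emax_a", True),
            ]
        )
        out, partition = flag_emergent(df)
        assert not out["emergent"].any()
        assert partition["total"] == 0

    def test_same_feature_other_subgroup_does_not_block(self):
        df = self._table(
            [
                assoc_row("F1", "c1", "pan", "bliss_matrix", True),
                assoc_row("F1", "c1", "basket", "emax_a", True),
            ]
        )
        out, _ = flag_emergent(df)
        assert out[(out["subgroup"] == "pan") & (out["metric"] == "bliss_matrix")][
            "emergent"
        ].all()

    def test_partition_is_disjoint_and_exhaustive(self):
        df = self._table(
            [
                assoc_row("F1", "c1", "pan", "bliss_matrix", True),
                assoc_row("F2", "c1", "pan", "combo_emax", True),
                assoc_row("F3", "c1", "pan", "bliss_matrix", True),
                assoc_row("F3", "c1", "pan", "combo_emax", True),
                assoc_row("F4", "c2", "pan", "bliss_window", True),
            ]
        )
        out, partition = flag_emergent(df)
        assert partition["bliss_only"] == 2  # F1 and F4 (window counts as Bliss)
        assert partition["both"] == 1
        assert partition["combo_emax_only"] == 1
        assert partition["total"] == 4
        n_groups = (
            out[out["emergent"]].groupby(["feature", "combo_id", "subgroup"]).ngroups
        )
        assert partition["total"] == n_groups

    def test_missing_single_agent_rows_rejected(self):
        df = self._table([assoc_row("F1", "c1", "pan", "bliss_matrix", True)])
        with pytest.raises(ValueError):
            flag_emergent(df[~df["metric"].isin(["emax_a", "emax_b"])])


class TestSubgroups:
    def test_cancer_type_minimum_size(self):
        ann = pd.DataFrame(
            {
                "cell_line": [f"c{i}" for i in range(50)],
                "cancer_type": ["big"] * 30 + ["small"] * 20,
            }
        )
        groups = build_subgroups(ann, min_cancer_type_size=21)
        kinds = {(g.id, g.kind) for g in groups}
        assert ("big", "cancer-type") in kinds
        assert ("small", "cancer-type") not in kinds
        assert ("pan-cancer", "pan-cancer") in kinds

    def test_basket_membership_from_feature(self):
        ann = pd.DataFrame(
            {"cell_line": ["a", "b", "c"], "cancer_type": ["x", "y", "z"]}
        )
        feats = pd.DataFrame(
            {"TP53_mut": [1, 0, 1]}, index=pd.Index(["a", "b", "c"], name="cell_line")
        )
        groups = build_subgroups(ann, feats, basket_features=("TP53_mut",))
        basket = [g for g in groups if g.kind == "basket"][0]
        assert set(basket.members) == {"a", "c"}

    def test_unknown_basket_feature_rejected(self):
        ann = pd.DataFrame({"cell_line": ["a"], "cancer_type": ["x"]})
        with pytest.raises(ValueError):
            build_subgroups(ann, None, basket_features=("NOPE",))
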