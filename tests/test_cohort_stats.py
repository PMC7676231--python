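"""Exclusions, indices, nutrition, odds ratios, correlations, FDR, forest."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imppipe import cohort_stats as cs
from imppipe.pipeline import _default_exclusion_rules
from imppipe.synthetic_data import SyntheticWorldConfig, simulate_cohort_truth


class TestGrubbs:
    def test_flags_the_planted_extreme(self):
        # G = 73.5 / 49.0 = 1.50 > critical 1.481 at n=4, alpha=0.05
        assert cs.grubbs_outliers([1, 2, 3, 100], alpha=0.05) == [3]

    def test_zero_variance_flags_nothing(self):
        assert cs.grubbs_outliers([1, 1, 1, 1]) == []

    def test_symmetric_small_sample_keeps_all(self):
        assert cs.grubbs_outliers([-5, 0, 5], alpha=0.05) == []

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            cs.grubbs_outliers([1, 2])


class TestExclusions:
    def test_planted_rule_hits_are_recovered(self):
        cfg = SyntheticWorldConfig(
            n_subjects=300, n_genes=600, n_mgs=8, mgs_size=50,
            n_nonmetabolic_cvd=5, n_imp_outliers=1, n_incomplete_biochem=3, seed=21,
        )
        cohort = simulate_cohort_truth(cfg).cohort_table()
        kept, acc = cs.apply_cohort_exclusions(cohort, _default_exclusion_rules())
        assert acc.counts == {
            "non_metabolic_cvd": 5,
            "imp_grubbs_outlier": 1,
            "incomplete_biochemistry": 3,
        }
        assert acc.n_retained == 291 == len(kept)
        assert sum(acc.counts.values()) == acc.n_input - acc.n_retained

    def test_empty_rule_list_rejected(self):
        with pytest.raises(ValueError):
            cs.apply_cohort_exclusions(pd.DataFrame({"a": [1]}), [])

    def test_overlapping_rules_count_once_under_first(self):
        df = pd.DataFrame({"x": [1, 5, 5, 2]})
        rules = [
            ("big", lambda d: d["x"] >= 5),
            ("also_big", lambda d: d["x"] >= 5),
        ]
        kept, acc = cs.apply_cohort_exclusions(df, rules)
        assert acc.counts == {"big": 2, "also_big": 0}
        assert len(kept) == 2


class TestDerivedIndices:
    def test_quicki_round_logs(self):
        # insulin 10 uU/ml, glucose 100 mg/dl -> 1 / (1 + 2) = 1/3
        rec = pd.DataFrame(
            {"glucose": [100 / 18.016], "insulin": [10.0], "triglycerides": [1.0]}
        )
        out = cs.derive_indices(rec)
        assert out["quicki"].iloc[0] == pytest.approx(1 / 3, abs=1e-9)

    def test_tyg_closed_form(self):
        # TG 150 mg/dl, glucose 100 mg/dl -> ln(7500)
        rec = pd.DataFrame(
            {"glucose": [100 / 18.016], "insulin": [10.0], "triglycerides": [150 / 88.57]}
        )
        assert cs.derive_indices(rec)["tyg"].iloc[0] == pytest.approx(np.log(7500), abs=1e-9)

    def test_homa_surrogate(self):
        rec = pd.DataFrame({"glucose": [5.0], "insulin": [9.0], "triglycerides": [1.0]})
        assert cs.derive_indices(rec)["homa_ir"].iloc[0] == pytest.approx(2.0)

    def test_nonpositive_analyte_named(self):
        rec = pd.DataFrame({"glucose": [-1.0], "insulin": [5.0], "triglycerides": [1.0]})
        with pytest.raises(ValueError, match="glucose"):
            cs.derive_indices(rec)

    def test_mdrd_female_factor(self):
        rec = pd.DataFrame(
            {
                "glucose": [5.0], "insulin": [8.0], "triglycerides": [1.2],
                "serum_creatinine": [0.9], "age": [50.0], "sex": ["female"],
            }
        )
        out = cs.derive_indices(rec)
        expected = 175 * 0.9**-1.154 * 50**-0.203 * 0.742
        assert out["mdrd_egfr"].iloc[0] == pytest.approx(expected)


class TestNutrition:
    def test_harris_benedict_reference_value(self):
        assert cs.harris_benedict_bmr("female", 70, 165, 50) == pytest.approx(1395.94, abs=0.01)

    def test_bmr_monotone_in_weight(self):
        b = [cs.harris_benedict_bmr("male", w, 180, 40) for w in (60, 80, 100)]
        assert b == sorted(b)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cs.harris_benedict_bmr("robot", 70, 165, 50)
        with pytest.raises(ValueError):
            cs.harris_benedict_bmr("male", 0, 165, 50)

    @pytest.mark.parametrize(
        "energy,expected", [(700, True), (750, False), (6000, True), (5250, False)]
    )
    def test_energy_plausibility_boundaries(self, energy, expected):
        assert cs.energy_intake_exclusion(energy, 1500) is expected

    def test_histidine_intake_units_and_additivity(self):
        comp = pd.Series({"meat": 20.0, "grain": 10.0})
        one = pd.Series({"meat": 100.0, "grain": 0.0})
        assert cs.compute_histidine_intake(one, comp) == pytest.approx(2.0)
        two = pd.Series({"meat": 50.0, "grain": 50.0})
        assert cs.compute_histidine_intake(two, comp) == pytest.approx(1.5)
        with pytest.raises(KeyError):
            cs.compute_histidine_intake(pd.Series({"mystery": 1.0}), comp)

    def test_diet_scores_dds_counts_nonzero_groups(self):
        from imppipe import foods

        intakes = pd.DataFrame(0.0, index=["a", "b"], columns=foods.GROUP_NAMES)
        intakes.loc["a", ["fruits", "vegetables", "eggs", "cheese", "water"]] = 50.0
        scores = cs.compute_diet_scores(intakes)
        assert scores.loc["a", "DDS"] == 5
        assert scores.loc["b", "DDS"] == 0
        assert scores.attrs["config_hash"]
        # adding intake in a new group never decreases DDS
        intakes.loc["b", "fruits"] = 10.0
        assert cs.compute_diet_scores(intakes).loc["b", "DDS"] == 1


class TestQuartiles:
    def test_even_split(self):
        labels = cs.quartile_stratify(np.arange(1, 9))
        assert labels.value_counts().sort_index().tolist() == [2, 2, 2, 2]

    def test_ties_go_low(self):
        labels = cs.quartile_stratify(np.ones(8))
        assert set(labels) == {"Q1"}

    def test_uniform_draws_balance(self, rng):
        labels = cs.quartile_stratify(rng.random(1000))
        counts = labels.value_counts()
        assert all(abs(counts[q] - 250) <= 1 for q in ["Q1", "Q2", "Q3", "Q4"])

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            cs.quartile_stratify([1, 2, 3])


def _two_by_two(a, b, c, d):
    """Q4/Q1 exposure x case/control outcome with the given cell counts."""
    outcome = (
        ["type2diabetes"] * a + ["healthy"] * b + ["type2diabetes"] * c + ["healthy"] * d
    )
    quartile = ["Q4"] * (a + b) + ["Q1"] * (c + d)
    idx = [f"s{i}" for i in range(len(outcome))]
    return pd.Series(outcome, index=idx), pd.Series(quartile, index=idx)


class TestMultinomialOr:
    def test_matches_cross_product_ratio(self):
        outcome, quart = _two_by_two(30, 10, 10, 30)
        res = cs.fit_multinomial_or(outcome, quart)[("type2diabetes", "Q4")]
        assert res.converged
        assert res.estimate == pytest.approx(9.0, rel=1e-6)
        assert res.ci_low < 9.0 < res.ci_high

    def test_null_exposure_or_near_one(self, rng):
        n = 2000
        outcome = pd.Series(rng.choice(["healthy", "type2diabetes"], n))
        quart = cs.quartile_stratify(pd.Series(rng.random(n)))
        res = cs.fit_multinomial_or(outcome, quart)[("type2diabetes", "Q4")]
        assert res.ci_low < 1.0 < res.ci_high

    def test_three_class_outcome_gives_all_contrasts(self, rng):
        n = 900
        outcome = pd.Series(
            rng.choice(["healthy", "prediabetes", "type2diabetes"], n)
        )
        quart = cs.quartile_stratify(pd.Series(rng.random(n)))
        out = cs.fit_multinomial_or(outcome, quart)
        assert set(out) == {
            (c, q)
            for c in ("prediabetes", "type2diabetes")
            for q in ("Q2", "Q3", "Q4")
        }


class TestPartialCorrelation:
    def test_no_covariates_equals_plain_correlation(self, rng):
        x, y = rng.normal(size=(2, 80))
        r = cs.partial_correlation(x, y)
        assert r.estimate == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_perfect_correlation(self):
        x = np.arange(20.0)
        r = cs.partial_correlation(x, x * 2 + 1)
        assert r.estimate == pytest.approx(1.0)

    def test_matches_pingouin_oracle(self, rng):
        import pingouin as pg

        n = 120
        z = rng.normal(size=(n, 2))
        x = z[:, 0] + rng.normal(size=n)
        y = z[:, 0] - 0.5 * z[:, 1] + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y, "c1": z[:, 0], "c2": z[:, 1]})
        ours = cs.partial_correlation(x, y, df[["c1", "c2"]])
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert ours.estimate == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert ours.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_spearman_matches_pingouin(self, rng):
        import pingouin as pg

        n = 90
        c = rng.normal(size=n)
        x = np.exp(c + rng.normal(size=n))
        y = c + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y, "c": c})
        ours = cs.partial_correlation(x, y, df[["c"]], method="spearman")
        ref = pg.partial_corr(df, x="x", y="y", covar=["c"], method="spearman")
        assert ours.estimate == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)

    def test_constant_extra_covariate_changes_nothing(self, rng):
        # a zero-variance diabetes-status column makes nested models identical
        n = 60
        covs = pd.DataFrame({"age": rng.normal(50, 8, n), "bmi": rng.normal(27, 4, n)})
        covs3 = covs.assign(status=1.0)
        x, y = rng.normal(size=(2, n))
        with pytest.warns(UserWarning):
            r3 = cs.partial_correlation(x, y, covs3)
        r2 = cs.partial_correlation(x, y, covs)
        assert r3.estimate == pytest.approx(r2.estimate, abs=1e-12)
        assert r3.p == pytest.approx(r2.p, abs=1e-12)


class TestFdrAndTransforms:
    def test_bh_hand_example(self):
        assert cs.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert cs.bh_fdr([0.2]) == pytest.approx([0.2])

    def test_q_monotone_in_sorted_p(self, rng):
        p = np.sort(rng.random(50))
        q = cs.bh_fdr(p)
        assert (np.diff(q) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            cs.bh_fdr([0.5, 1.2])

    def test_lognormal_sample_is_transformed(self, rng):
        res = cs.log_transform_policy(rng.lognormal(0, 1, 200))
        assert res.transformed and not res.degenerate

    def test_normal_sample_not_transformed(self, rng):
        res = cs.log_transform_policy(rng.normal(10, 1, 200))
        assert not res.transformed

    def test_constant_vector_flagged_degenerate(self):
        res = cs.log_transform_policy(np.full(30, 7.0))
        assert res.degenerate and not res.transformed


class TestLinearGroupComparison:
    def test_two_groups_equals_t_test(self, rng):
        y = np.concatenate([rng.normal(0, 1, 30), rng.normal(0.4, 1, 25)])
        group = pd.Series(["healthy"] * 30 + ["type2diabetes"] * 25)
        res = cs.linear_group_comparison(pd.Series(y), group)
        t = stats.ttest_ind(y[30:], y[:30])
        assert res.p == pytest.approx(t.pvalue, abs=1e-10)
        assert res.estimate == pytest.approx(y[30:].mean() - y[:30].mean(), abs=1e-10)

    def test_planted_shift_detected(self, rng):
        shift = {"healthy": 0.0, "prediabetes": 0.25, "type2diabetes": 0.5}
        group = pd.Series(rng.choice(list(shift), 600))
        y = pd.Series([shift[g] for g in group]) + rng.normal(0, 1, 600)
        res = cs.linear_group_comparison(y, group)
        assert res.p < 0.05
        assert res.extra["coefficients"]["group_type2diabetes"] > 0


class TestRandomForest:
    def test_planted_taxa_rank_high_and_constant_ranks_low(self, rng):
        n, p = 250, 40
        X = pd.DataFrame(
            rng.normal(size=(n, p)), columns=[f"taxon_{j}" for j in range(p)]
        )
        X["taxon_39"] = 1.0  # zero variance
        causal = ["taxon_0", "taxon_1", "taxon_2"]
        y = X[causal].sum(axis=1) * 0.8 + rng.normal(0, 1, n)
        cfg = cs.RFConfig(n_folds=10, n_trees=60, seed=1)
        table = cs.rf_motu_importance(y, X, cfg)
        top10 = set(table.index[:10])
        assert set(causal) <= top10
        assert table.loc["taxon_39", "importance"] == pytest.approx(0.0, abs=1e-12)
        assert {"importance", "spearman_rho", "p", "q"} <= set(table.columns)

    def test_fold_count_reduced_with_warning(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        y = rng.normal(size=20)
        with pytest.warns(UserWarning, match="folds"):
            cs.rf_motu_importance(y, X, cs.RFConfig(n_folds=100, n_trees=10))
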