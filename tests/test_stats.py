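import numpy as np
import pytest
from scipy import stats as sps

from gaitscore.core import GaitScoreError, PlanningError, SchemaError
from gaitscore.stats import (
    cohens_d,
    compute_metrics,
    make_cv_plan,
    mcnemar,
    paired_t_folds,
    posthoc_power,
    run_experiment,
)

DEFAULT_LEVELS = [0] * 10 + [1] * 5 + [2] * 6


class TestCVPlan:
    def test_default_protocol_counts(self):
        plan = make_cv_plan(DEFAULT_LEVELS, seed=0)
        assert plan.n_folds == 21
        assert sum(len(test) for _, test in plan.folds) == 84
        for train, test in plan.folds:
            assert set(train).isdisjoint(test)
            levels = [DEFAULT_LEVELS[i] for i in test]
            assert sorted(levels) == [0, 0, 1, 2]

    def test_every_subject_appears_at_least_twice(self):
        plan = make_cv_plan(DEFAULT_LEVELS, seed=0)
        counts = np.zeros(21, dtype=int)
        for _, test in plan.folds:
            counts[list(test)] += 1
        assert counts.min() >= 2

    def test_deterministic_given_seed(self):
        a = make_cv_plan(DEFAULT_LEVELS, seed=3)
        b = make_cv_plan(DEFAULT_LEVELS, seed=3)
        assert a.folds == b.folds

    def test_forced_minimal_cohort(self):
        plan = make_cv_plan([0, 0, 1, 2], seed=0, n_folds=4)
        for _, test in plan.folds:
            assert test == (0, 1, 2, 3)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(PlanningError):
            make_cv_plan([0, 1, 2], seed=0)


class TestMetrics:
    def test_perfect_predictions(self):
        rep = compute_metrics([0, 1, 2, 1], [0, 1, 2, 1])
        assert rep.overall_accuracy == 1.0
        np.testing.assert_array_equal(rep.precision, [1, 1, 1])
        np.testing.assert_array_equal(rep.recall, [1, 1, 1])

    def test_hand_counted_confusion(self):
        # rows = truth: [[2,0,0],[0,1,1],[0,0,2]]
        y_true = [0, 0, 1, 1, 2, 2]
        y_pred = [0, 0, 1, 2, 2, 2]
        rep = compute_metrics(y_pred, y_true)
        np.testing.assert_array_equal(rep.confusion_matrix,
                                      [[2, 0, 0], [0, 1, 1], [0, 0, 2]])
        assert rep.overall_accuracy == pytest.approx(5 / 6)
        assert rep.recall[1] == pytest.approx(0.5)
        assert rep.precision[2] == pytest.approx(2 / 3)

    def test_undefined_precision_reported_as_zero(self):
        rep = compute_metrics([0, 0, 0], [0, 0, 0])
        assert rep.precision[1] == 0.0 and rep.recall[1] == 0.0

    def test_accuracy_times_n_equals_trace(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 3, 50)
        y_pred = rng.integers(0, 3, 50)
        rep = compute_metrics(y_pred, y_true)
        assert rep.overall_accuracy * 50 == pytest.approx(
            np.trace(rep.confusion_matrix))


class TestPairedT:
    def test_agrees_with_direct_formula_and_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.random(21)
            b = rng.random(21)
            t, df, p, mean_diff, ci = paired_t_folds(a, b)
            d = a - b
            t_direct = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            assert t == pytest.approx(t_direct, abs=1e-12)
            assert df == 20
            t_sp, p_sp = sps.ttest_rel(a, b)
            assert t == pytest.approx(t_sp, abs=1e-12)
            assert p == pytest.approx(p_sp, abs=1e-12)
            assert ci[0] < mean_diff < ci[1]

    def test_zero_variance_differences_degenerate(self):
        a = np.linspace(0.5, 0.9, 10)
        with pytest.raises(GaitScoreError):
            paired_t_folds(a, a)  # all-zero differences
        with pytest.raises(GaitScoreError):
            paired_t_folds(a + 0.1, a)  # constant +0.1 differences

    def test_mean_diff_is_difference_of_means(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(21), rng.random(21)
        *_, mean_diff, _ = paired_t_folds(a, b)
        assert mean_diff == pytest.approx(a.mean() - b.mean(), abs=1e-12)


class TestMcNemar:
    def test_formula_evaluation(self):
        chi2, _ = mcnemar(2, 10)
        assert chi2 == pytest.approx((8 - 1) ** 2 / 12, abs=1e-12)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for a, b in ((1, 24), (5, 9), (13, 2)):
            chi2, p = mcnemar(a, b)
            table = [[0, a], [b, 0]]
            res = sm_mcnemar(table, exact=False, correction=True)
            assert chi2 == pytest.approx(res.statistic, abs=1e-10)
            assert p == pytest.approx(res.pvalue, abs=1e-10)

    def test_no_discordant_pairs_rejected(self):
        with pytest.raises(GaitScoreError):
            mcnemar(0, 0)


class TestCohensD:
    def test_hand_computed_example(self):
        assert cohens_d([1, 2, 3], [4, 5, 6]) == pytest.approx(-3.0)

    def test_identical_groups(self):
        assert cohens_d([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]) == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(8), rng.random(12)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a), abs=1e-12)

    def test_agrees_with_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(2)
        a, b = rng.random(10), rng.random(12) + 0.3
        expected = pg.compute_effsize(a, b, eftype="cohen")
        assert cohens_d(a, b) == pytest.approx(expected, abs=1e-10)


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert posthoc_power(0.0, 10, 10) == pytest.approx(0.05, abs=1e-9)

    def test_large_effect_near_one(self):
        assert posthoc_power(3.0, 10, 10) > 0.99

    def test_monotone_in_effect_and_n(self):
        ds = [posthoc_power(d, 10, 10) for d in (0.2, 0.5, 1.0, 2.0)]
        assert all(np.diff(ds) > 0)
        ns = [posthoc_power(0.8, n, n) for n in (5, 10, 20, 40)]
        assert all(np.diff(ns) > 0)

    def test_agrees_with_pingouin(self):
        import pingouin as pg

        for d, na, nb in ((0.8, 10, 10), (1.46, 10, 6), (2.74, 10, 6)):
            expected = pg.power_ttest2n(nx=na, ny=nb, d=d, alpha=0.05)
            assert posthoc_power(d, na, nb) == pytest.approx(expected, abs=1e-8)


class TestRunExperiment:
    def test_accounting_identities_on_small_cohort(self, small_cohort_features):
        feats, labels = small_cohort_features
        report = run_experiment(feats, labels, seed=0, n_folds=4)
        n_pred = len(report.pooled_labels)
        assert n_pred == 4 * 4  # folds × test subjects
        a, b = report.mcnemar_counts
        correct_base = report.baseline.overall_accuracy * n_pred
        correct_fused = report.fusion.overall_accuracy * n_pred
        assert b - a == pytest.approx(correct_fused - correct_base, abs=1e-9)
        assert report.ablation_matrix.shape == (4, 4)
        assert set(report.occlusion) == {"ta_l", "ta_r", "ga_l", "ga_r"}
        # confusion-matrix row sums equal per-class test counts
        for rep in (report.baseline, report.fusion):
            np.testing.assert_array_equal(
                rep.confusion_matrix.sum(axis=1),
                np.bincount(report.pooled_labels, minlength=3))
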