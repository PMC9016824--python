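"""CV logistic classification, ROC analysis, and group statistics."""

import numpy as np
import pytest
from scipy import stats

from aqipet import evaluate as ev


class TestStratifiedFolds:
    def test_balanced_100_subjects_give_5_plus_5_per_fold(self):
        y = np.array([1] * 50 + [0] * 50)
        folds = ev.stratified_folds(y, 10, rng=0)
        for f in range(10):
            assert np.sum((folds == f) & (y == 1)) == 5
            assert np.sum((folds == f) & (y == 0)) == 5

    def test_too_many_folds_errors(self):
        y = np.array([1, 1, 0, 0, 0])
        with pytest.raises(ValueError, match="fewer than"):
            ev.stratified_folds(y, 3, rng=0)

    def test_same_seed_same_folds(self):
        y = np.array([1] * 20 + [0] * 20)
        a = ev.stratified_folds(y, 5, rng=7)
        b = ev.stratified_folds(y, 5, rng=7)
        assert np.array_equal(a, b)


class TestFitLogistic:
    def test_separated_data_finite_weights_perfect_training_accuracy(self):
        x = np.array([0.0, 1, 2, 3, 10, 11, 12, 13])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        m = ev.fit_logistic(x, y)
        assert np.all(np.isfinite(m.weights)) and np.isfinite(m.intercept)
        assert np.mean((m.predict_proba(x) >= 0.5) == y) == 1.0

    def test_null_relationship_weight_within_three_se(self):
        rng = np.random.default_rng(123)
        x = rng.normal(size=400)
        y = rng.integers(0, 2, size=400)  # independent of x
        m = ev.fit_logistic(x, y)
        assert abs(m.weights[0]) < 3.0 * m.se[1]

    def test_constant_feature_balanced_labels_gives_null_model(self):
        x = np.zeros(40)
        y = np.array([0, 1] * 20)
        m = ev.fit_logistic(x, y)
        assert m.intercept == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(m.predict_proba(x), 0.5, atol=1e-6)

    def test_matches_statsmodels_on_well_conditioned_data(self):
        # independent cross-check against an established GLM implementation
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        p = 1.0 / (1.0 + np.exp(-(0.3 + 1.2 * x)))
        y = (rng.uniform(size=300) < p).astype(float)
        ours = ev.fit_logistic(x, y, ridge=1e-10)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert ours.intercept == pytest.approx(ref.params[0], abs=1e-5)
        assert ours.weights[0] == pytest.approx(ref.params[1], abs=1e-5)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            ev.fit_logistic(np.arange(4.0), np.ones(4))


def _pairwise_auc(scores, labels):
    """Brute-force AUC: fraction of (positive, negative) pairs correctly
    ordered, ties counting one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAnalysis:
    def test_worked_four_point_example(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        assert ev.roc_analysis(scores, labels).auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        r = ev.roc_analysis(np.array([1.0, 2, 9, 10]), np.array([0, 0, 1, 1]))
        assert (r.auc, r.sensitivity, r.specificity, r.accuracy) == (1, 1, 1, 1)

    def test_negation_symmetry(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=30)
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        a1 = ev.roc_analysis(s, y).auc
        a2 = ev.roc_analysis(-s, y).auc
        assert a1 + a2 == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(20))
    def test_auc_equals_exhaustive_pairwise_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(4, 51))
        # coarse scores force ties
        s = np.round(rng.normal(size=n), 1)
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]
        assert ev.roc_analysis(s, y).auc == pytest.approx(_pairwise_auc(s, y))

    def test_matches_sklearn_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(77)
        s = np.round(rng.normal(size=200), 1)
        y = rng.integers(0, 2, size=200)
        y[:2] = [0, 1]
        assert ev.roc_analysis(s, y).auc == pytest.approx(roc_auc_score(y, s))

    def test_accuracy_consistency_and_majority_bound(self):
        # on balanced classes (the study design) the Youden-optimal point can
        # never do worse than the majority rule: accuracy = (J + 1) / 2 >= 1/2
        rng = np.random.default_rng(9)
        for _ in range(20):
            half = int(rng.integers(3, 20))
            n = 2 * half
            s = np.round(rng.normal(size=n), 1)
            y = np.array([0] * half + [1] * half)
            r = ev.roc_analysis(s, y)
            assert r.accuracy == pytest.approx(
                (r.sensitivity * half + r.specificity * half) / n
            )
            assert r.accuracy >= 0.5 - 1e-12

    def test_one_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            ev.roc_analysis(np.arange(3.0), np.zeros(3))


class TestCrossvalidate:
    def test_perfect_feature(self):
        y = np.array([0, 1] * 20)
        cv = ev.crossvalidate(y.astype(float), y, k=5, rng=0)
        assert cv.roc.auc == 1.0
        assert cv.accuracy == 1.0

    def test_null_feature_auc_near_half(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=100)
        y = np.array([0, 1] * 50)
        cv = ev.crossvalidate(x, y, k=10, rng=2)
        assert 0.35 <= cv.roc.auc <= 0.65

    def test_measure_scale_threshold_separates_like_score_threshold(self):
        rng = np.random.default_rng(12)
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(3, 1, 50)])
        y = np.array([0] * 50 + [1] * 50)
        cv = ev.crossvalidate(x, y, k=10, rng=3)
        thr = cv.measure_threshold
        acc = np.mean((x >= thr) == y)
        assert acc == pytest.approx(cv.accuracy, abs=0.05)


class TestStatistics:
    def test_cohens_d_hand_example(self):
        assert ev.cohens_d([4, 5, 6], [1, 2, 3]) == pytest.approx(3.0)

    def test_cohens_d_identical_groups_zero(self):
        assert ev.cohens_d([1.0, 2, 3], [1.0, 2, 3]) == pytest.approx(0.0)

    def test_cohens_d_antisymmetry(self):
        assert ev.cohens_d([1, 2, 3], [4, 5, 6]) == pytest.approx(-3.0)

    def test_kruskal_wallis_hand_example(self):
        h, p = ev.kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(3.857, abs=5e-4)
        assert p == pytest.approx(stats.chi2.sf(h, 1))

    def test_kruskal_wallis_identical_groups(self):
        h, p = ev.kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert (h, p) == (0.0, 1.0)

    def test_kruskal_wallis_same_multiset_zero(self):
        h, _ = ev.kruskal_wallis([[1, 2, 3], [3, 1, 2]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_pearson_perfect_and_antiperfect(self):
        x = np.array([1.0, 2, 5, 7])
        assert ev.pearson_corr(x, x)[0] == pytest.approx(1.0)
        assert ev.pearson_corr(x, -x)[0] == pytest.approx(-1.0)

    def test_pearson_four_point_example(self):
        # r = 11 / sqrt(5 * 26) for (1,2,3,4) vs (2,4,5,9)
        r, p = ev.pearson_corr([1, 2, 3, 4], [2, 4, 5, 9])
        assert r == pytest.approx(11.0 / np.sqrt(130.0), abs=5e-5)
        assert r == pytest.approx(0.9648, abs=5e-5)

    def test_pearson_drops_nan_pairs(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, 8.0, 10.0]
        r, _ = ev.pearson_corr(x, y)
        assert r == pytest.approx(1.0)

    def test_pearson_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            ev.pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestEvaluateMeasure:
    def test_report_fields_consistent(self):
        rng = np.random.default_rng(21)
        y = np.array([0] * 30 + [1] * 30)
        x = y * 2.0 + rng.normal(0, 0.5, 60)
        mmse = 30.0 - 3.0 * x + rng.normal(0, 1, 60)
        rep = ev.evaluate_measure(x, y, k=5, rng=4, mmse=mmse, measure_name="m")
        n1 = n0 = 30
        assert rep.accuracy == pytest.approx(
            (rep.sensitivity * n1 + rep.specificity * n0) / 60
        )
        assert rep.effect_size > 1.0
        assert rep.kw_p < 0.001
        assert rep.corr_mmse[0] < -0.5
        d = rep.to_dict()
        assert d["measure"] == "m" and d["corr_cdr_sob"] is None

    def test_threshold_metrics_holdout(self):
        vals = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        rep = ev.threshold_metrics(vals, labels, 0.5)
        assert (rep.sensitivity, rep.specificity, rep.accuracy) == (1, 1, 1)
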