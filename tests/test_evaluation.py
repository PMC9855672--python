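"""ROC/AUC machinery, ANOVA notation, repeated splits, size stratification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from echodsi import (
    SplitPlan,
    anova_p,
    evaluate_cohort,
    make_splits,
    operating_metrics,
    roc_auc,
    size_stratified_eval,
    youden_threshold,
)
from echodsi.evaluation import significance_notation


def brute_force_auc(scores, labels):
    """Pairwise-concordance oracle with half credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels != 1]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_and_chance_scores(self):
        y = np.array([-1, -1, 1, 1])
        assert roc_auc(y.astype(float), y, ci=False) == 1.0
        assert roc_auc(np.zeros(4), y, ci=False) == 0.5

    def test_worked_four_case_example(self):
        # concordant pairs: 3 of 4 -> AUC = 0.75
        auc = roc_auc([0.1, 0.4, 0.35, 0.8], [-1, -1, 1, 1], ci=False)
        assert auc == 0.75

    def test_matches_brute_force_concordance(self, rng):
        for _ in range(25):
            n = rng.integers(4, 50)
            y = np.where(rng.random(n) > 0.5, 1, -1)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
            assert roc_auc(s, y, ci=False) == brute_force_auc(s, y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_delong_ci_contains_point_estimate(self, rng):
        y = np.array([-1] * 30 + [1] * 30)
        s = np.concatenate([rng.normal(0, 1, 30), rng.normal(1, 1, 30)])
        auc, (lo, hi) = roc_auc(s, y)
        assert lo <= auc <= hi
        assert 0.0 <= lo and hi <= 1.0

    def test_delong_ci_coverage_on_binormal_scores(self):
        # known AUC = Phi(mu/sqrt(2)) for unit-variance binormal scores
        mu = 1.0
        true_auc = stats.norm.cdf(mu / np.sqrt(2))
        hits = 0
        reps = 500
        rng = np.random.default_rng(0)
        for _ in range(reps):
            s = np.concatenate([rng.normal(0, 1, 40), rng.normal(mu, 1, 40)])
            y = np.array([-1] * 40 + [1] * 40)
            _, (lo, hi) = roc_auc(s, y)
            hits += lo <= true_auc <= hi
        assert hits / reps >= 0.90


class TestOperatingMetrics:
    def test_perfect_separation(self):
        y = np.array([-1, -1, 1, 1])
        s = np.array([0.0, 0.1, 0.9, 1.0])
        thr = youden_threshold(s, y)
        out = operating_metrics(s, y, thr)
        assert (out["accuracy"], out["sensitivity"], out["specificity"]) == (1, 1, 1)

    def test_all_predicted_positive(self):
        y = np.array([-1, -1, 1, 1])
        out = operating_metrics(np.ones(4), y, threshold=0.0)
        assert out["sensitivity"] == 1.0 and out["specificity"] == 0.0

    def test_worked_confusion_matrix(self):
        out = operating_metrics([1, 2, 3, 4], [-1, -1, 1, 1], threshold=2.5)
        assert (out["accuracy"], out["sensitivity"], out["specificity"]) == (1, 1, 1)

    def test_empty_class_reports_nan_not_zero(self):
        out = operating_metrics([1.0, 2.0], [1, 1], threshold=1.5)
        assert np.isnan(out["specificity"]) and out["sensitivity"] == 0.5


class TestAnova:
    def test_identical_groups_not_significant(self):
        p, note = anova_p([1, 2, 3, 1, 2, 3], [-1, -1, -1, 1, 1, 1])
        assert p == 1.0 and note == "ns"

    def test_worked_f8_example(self):
        # groups (1,2) vs (3,4): F = 8 on (1,2) df, p ~ 0.1056 -> ns
        p, note = anova_p([1, 2, 3, 4], [-1, -1, 1, 1])
        assert np.isclose(p, 0.10557, atol=5e-5)
        assert note == "ns"

    def test_notation_cut_points(self):
        assert significance_notation(0.2) == "ns"
        assert significance_notation(0.03) == "*"
        assert significance_notation(0.005) == "**"
        assert significance_notation(0.0009) == "***"
        assert significance_notation(5e-5) == "****"

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_p([2.0, 2.0, 2.0, 2.0], [-1, -1, 1, 1])
        with pytest.raises(ValueError):
            anova_p([1.0, 2.0, 3.0], [-1, -1, 1])


class TestSplits:
    def test_70_30_sizes(self):
        y = np.array([-1] * 50 + [1] * 50)
        for train, test in make_splits(y, SplitPlan()):
            assert len(train) == 70 and len(test) == 30
            assert len(np.intersect1d(train, test)) == 0
            assert len(np.union1d(train, test)) == 100

    def test_same_seeds_reproduce_splits(self):
        y = np.array([-1] * 20 + [1] * 20)
        a = make_splits(y, SplitPlan(seeds=(3, 4)))
        b = make_splits(y, SplitPlan(seeds=(3, 4)))
        for (ta, _), (tb, _) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)

    def test_stratification_keeps_class_proportions(self):
        y = np.array([-1] * 36 + [1] * 24)
        for train, _ in make_splits(y, SplitPlan()):
            n_pos = np.sum(y[train] == 1)
            expect = 0.7 * 24
            assert abs(n_pos - expect) <= 1

    def test_too_small_class_rejected(self):
        with pytest.raises(ValueError):
            make_splits(np.array([-1, -1, -1, 1]), SplitPlan())


class TestProtocol:
    @staticmethod
    def _feature_cohort(seed=0, n=60, sep=2.0):
        rng = np.random.default_rng(seed)
        y = np.array([-1] * (n // 2) + [1] * (n // 2))
        cols = {}
        from echodsi.features import SELECTED_FEATURES

        for name in SELECTED_FEATURES:
            shift = np.where(y == 1, sep, 0.0)
            cols[name] = rng.normal(0, 1, n) + shift
        df = pd.DataFrame(cols)
        return df, y

    def test_no_leakage_of_test_labels_into_fitting(self):
        df, y = self._feature_cohort()
        plan = SplitPlan(seeds=(0,))
        (train, test), = make_splits(y, plan)
        from echodsi import DSIModel
        from echodsi.features import SELECTED_FEATURES

        m1 = DSIModel(feature_names=list(SELECTED_FEATURES), seed=0).fit(
            df.iloc[train], y[train]
        )
        y_shuffled = y.copy()
        y_shuffled[test] = np.random.default_rng(0).permutation(y[test])
        m2 = DSIModel(feature_names=list(SELECTED_FEATURES), seed=0).fit(
            df.iloc[train], y_shuffled[train]
        )
        assert m1.to_json() == m2.to_json()

    def test_summary_aggregates_five_splits(self):
        df, y = self._feature_cohort()
        rep = evaluate_cohort(df, y)
        assert set(rep.per_split["split"]) == {0, 1, 2, 3, 4}
        test_rows = rep.summary[rep.summary["set"] == "test"]
        assert len(test_rows) == 3  # one per combiner
        assert (test_rows["auc_mean"] > 0.8).all()

    def test_size_threshold_zero_keeps_full_cohort(self):
        df, y = self._feature_cohort()
        areas = np.linspace(0.05, 2.0, len(y))
        tbl = size_stratified_eval(df, y, areas, thresholds=(0.0,), plan=SplitPlan(seeds=(0,)))
        assert tbl.iloc[0]["n_cases"] == len(y)

    def test_threshold_above_max_area_marked_insufficient(self):
        df, y = self._feature_cohort()
        areas = np.full(len(y), 0.5)
        tbl = size_stratified_eval(df, y, areas, thresholds=(0.5, 1.0))
        assert tbl["insufficient"].all()  # strict inequality: area > 0.5 fails too

    def test_auc_improves_with_size_when_effect_scales_with_area(self):
        # larger lesions separate better; AUC should trend upward with the
        # size threshold (averaged over seeds)
        from echodsi.features import SELECTED_FEATURES

        n = 120
        deltas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.array([-1] * (n // 2) + [1] * (n // 2))
            areas = rng.uniform(0.05, 1.5, n)
            areas[y == 1] += 0.3  # malignant lesions tend larger
            cols = {}
            for name in SELECTED_FEATURES:
                effect = np.where(y == 1, 1.2 * areas, 0.0)
                cols[name] = rng.normal(0, 1, n) + effect
            df = pd.DataFrame(cols)
            lo = roc_auc(df.sum(axis=1)[areas > 0.1], y[areas > 0.1], ci=False)
            hi = roc_auc(df.sum(axis=1)[areas > 0.9], y[areas > 0.9], ci=False)
            deltas.append(hi - lo)
        assert np.mean(deltas) > 0
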