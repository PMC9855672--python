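"""PC1 / projection / SVM-distance combiners and feature-subset selection."""

import numpy as np
import pandas as pd
import pytest

from echodsi import DSIModel, PC1Scorer, ProjectionScorer, SVMDistanceScorer, select_features
from echodsi.scoring import fit_standardizer, projection_score, svm_distance, train_svm


def _blobs(n=40, sep=4.0, d=2, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([
        rng.normal(0.0, 1.0, (n, d)),
        rng.normal(sep, 1.0, (n, d)),
    ])
    y = np.array([-1] * n + [1] * n)
    return X, y


class TestStandardizer:
    def test_standardized_table_has_zero_mean_unit_std(self, rng):
        df = pd.DataFrame(rng.normal(5, 3, (50, 4)), columns=list("abcd"))
        mu, sigma, z = fit_standardizer(df)
        assert np.all(np.abs(z.mean(axis=0)) < 1e-12)
        assert np.allclose(z.std(axis=0, ddof=0), 1.0)

    def test_already_standardized_returns_identity_params(self, rng):
        z0 = rng.standard_normal((200, 3))
        z0 = (z0 - z0.mean(0)) / z0.std(0)
        mu, sigma, _ = fit_standardizer(pd.DataFrame(z0))
        assert np.allclose(mu, 0, atol=1e-12) and np.allclose(sigma, 1, atol=1e-12)

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            fit_standardizer(df)


class TestPC1:
    def test_perfectly_correlated_features_split_contributions_evenly(self):
        rng = np.random.default_rng(0)
        t = rng.standard_normal(100)
        X = np.column_stack([t, t])
        y = np.where(t > 0, 1, -1)
        sc = PC1Scorer().fit(X, y)
        assert np.allclose(sc.contributions_, [0.5, 0.5])
        assert sc.explained_variance_ratio_ > 0.999

    def test_contributions_sum_to_one(self, rng):
        X = rng.standard_normal((60, 5))
        y = np.array([-1, 1] * 30)
        sc = PC1Scorer().fit(X, y)
        assert np.isclose(sc.contributions_.sum(), 1.0)
        assert np.all(sc.contributions_ >= 0)

    def test_pc1_has_maximal_variance_among_random_directions(self, rng):
        X = rng.standard_normal((80, 5)) @ np.diag([3, 2, 1, 1, 0.5])
        y = np.array([-1, 1] * 40)
        sc = PC1Scorer().fit(X, y)
        Z = (X - sc.mean_) / sc.scale_
        var_pc1 = np.var(Z @ sc.loadings_)
        dirs = rng.standard_normal((1000, 5))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        assert var_pc1 >= np.var(Z @ dirs.T, axis=0).max() - 1e-12

    def test_malignant_mean_score_above_benign(self):
        X, y = _blobs(d=5, seed=3)
        s = PC1Scorer().fit(X, y).decision_function(X)
        assert s[y == 1].mean() > s[y == -1].mean()


class TestProjection:
    def test_unit_vector_inner_products(self):
        u = np.array([1.0, 0.0, 0.0])
        assert np.isclose(projection_score(u, u)[0], 1.0)
        assert np.isclose(projection_score([0.0, 1.0, 0.0], u)[0], 0.0)

    def test_zero_or_non_unit_reference_rejected(self):
        with pytest.raises(ValueError):
            projection_score([1.0, 0.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            projection_score([1.0, 0.0], [2.0, 0.0])

    def test_centroid_score_gap_equals_centroid_distance(self):
        X, y = _blobs(d=3, seed=5)
        sc = ProjectionScorer().fit(X, y)
        Z = (X - sc.mean_) / sc.scale_
        mb = Z[y == -1].mean(axis=0)
        mm = Z[y == 1].mean(axis=0)
        gap = (mm - mb) @ sc.reference_direction_
        assert np.isclose(gap, np.linalg.norm(mm - mb))


class TestSVM:
    def test_separable_blobs_reach_perfect_training_accuracy(self):
        X, y = _blobs(sep=6.0, seed=1)
        sc = SVMDistanceScorer(seed=0).fit(X, y)
        assert np.all(sc.predict(X) == y)

    def test_label_permutation_gives_chance_level_cv(self):
        X, y = _blobs(sep=6.0, seed=2)
        rng = np.random.default_rng(0)
        sc = SVMDistanceScorer(seed=0).fit(X, rng.permutation(y))
        assert 0.35 <= sc.cv_accuracy_ <= 0.65

    def test_fixed_seed_selects_identical_hyperparameters(self):
        X, y = _blobs(seed=4)
        a = SVMDistanceScorer(seed=9).fit(X, y)
        b = SVMDistanceScorer(seed=9).fit(X, y)
        assert (a.box_, a.gamma_) == (b.box_, b.gamma_)
        np.testing.assert_array_equal(a.dual_coef_, b.dual_coef_)

    def test_sign_matches_predicted_class(self):
        X, y = _blobs(sep=6.0, seed=1)
        sc = SVMDistanceScorer(seed=0).fit(X, y)
        d = sc.decision_function(X)
        assert np.all(np.sign(d[d != 0]) == sc.predict(X)[d != 0])

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 2))
        with pytest.raises(ValueError):
            SVMDistanceScorer().fit(X, np.ones(10, dtype=int))

    def test_geometric_distance_matches_dense_grid_oracle(self):
        X, y = _blobs(n=30, sep=4.0, d=2, seed=7)
        sc = SVMDistanceScorer(seed=0).fit(X, y)
        # oracle: sign changes of the decision value on a dense grid
        lim = 4.0
        res = 0.02
        gx = np.arange(-lim, lim + sc.mean_[0] + 4, res)
        gy = np.arange(-lim, lim + sc.mean_[1] + 4, res)
        GX, GY = np.meshgrid(gx, gy)
        Zg = np.column_stack([GX.ravel(), GY.ravel()])
        fg = sc._decision_standardized(Zg).reshape(GX.shape)
        sign_change = np.zeros_like(fg, dtype=bool)
        sign_change[:-1] |= np.sign(fg[:-1]) != np.sign(fg[1:])
        sign_change[:, :-1] |= np.sign(fg[:, :-1]) != np.sign(fg[:, 1:])
        surf = Zg.reshape(*GX.shape, 2)[sign_change]
        test_points = X[::10]
        geo = sc.geometric_distance(test_points)
        Zt = (test_points - sc.mean_) / sc.scale_
        for z, g in zip(Zt, geo):
            brute = np.min(np.linalg.norm(surf - z, axis=1))
            assert abs(abs(g) - brute) < 3 * res

    def test_svm_distance_wrapper_modes(self):
        X, y = _blobs(sep=6.0, seed=1)
        sc = train_svm(pd.DataFrame(X), y, seed=0)
        d = svm_distance(sc, X[:5])
        g = svm_distance(sc, X[:5], mode="geometric")
        assert np.all(np.sign(d) == np.sign(g))
        with pytest.raises(ValueError):
            svm_distance(sc, X[:5], mode="nope")


class TestFeatureSelection:
    def test_enumerates_511_subsets_and_finds_planted_feature(self, rng):
        n = 80
        informative = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(4, 1, n // 2)])
        y = np.array([-1] * (n // 2) + [1] * (n // 2))
        data = {f"noise_{i}": rng.standard_normal(n) for i in range(8)}
        data["informative"] = informative
        df = pd.DataFrame(data)
        out = select_features(df, y, scorer="pc1")
        assert out["n_subsets"] == 511
        assert "informative" in out["best_subset"]

    def test_best_subset_beats_every_singleton(self, strong_table):
        from echodsi.features import FEATURE_NAMES

        y = strong_table["label"].to_numpy()
        out = select_features(strong_table[list(FEATURE_NAMES)], y, scorer="pc1")
        for name in FEATURE_NAMES:
            single = [r for r in out["table"] if r["subset"] == (name,)]
            assert out["best_auc"] >= single[0]["auc"]


class TestDSIModel:
    def test_monotone_class_contract_on_strong_cohort(self, strong_table):
        from echodsi.features import SELECTED_FEATURES

        y = strong_table["label"].to_numpy()
        model = DSIModel(feature_names=list(SELECTED_FEATURES), seed=0).fit(strong_table, y)
        trip = model.score_triplet(strong_table)
        for comb in ("pc1", "projection", "svm_distance"):
            s = trip[comb].to_numpy()
            assert s[y == 1].mean() > s[y == -1].mean()

    def test_json_roundtrip_preserves_scores(self):
        X, y = _blobs(d=5, seed=8)
        df = pd.DataFrame(X, columns=list("abcde"))
        model = DSIModel(feature_names=list("abcde"), seed=0).fit(df, y)
        clone = DSIModel.from_json(model.to_json())
        for comb in ("pc1", "projection", "svm_distance"):
            np.testing.assert_allclose(
                model.decision_function(df, combiner=comb),
                clone.decision_function(df, combiner=comb),
                rtol=1e-12,
            )

    def test_identical_fits_serialize_identically(self):
        X, y = _blobs(d=5, seed=8)
        df = pd.DataFrame(X, columns=list("abcde"))
        a = DSIModel(feature_names=list("abcde"), seed=3).fit(df, y).to_json()
        b = DSIModel(feature_names=list("abcde"), seed=3).fit(df, y).to_json()
        assert a == b
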