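"""Multiparametric combination of lesion features into malignancy scores.

Three scalar combiners over standardized features are provided, each as a
scikit-learn style estimator (``fit`` / ``decision_function`` / ``predict``):

* :class:`PC1Scorer` — first principal component of the training features,
  sign-oriented so malignant (+1) scores above benign (−1);
* :class:`ProjectionScorer` — inner product with a unit reference direction,
  the standardized benign→malignant centroid direction;
* :class:`SVMDistanceScorer` — signed distance to a Gaussian-kernel SVM
  hyperplane. The default "distance" is the signed kernel decision value
  (zero exactly on the hyperplane, sign = predicted class); a geometric
  mode returns the Euclidean distance in standardized feature space to the
  nearest point of the decision surface.

:class:`DSIModel` bundles the three scorers with a shared standardization
and clipping limits for probability mapping, and round-trips through JSON.
Labels are −1 (benign) and +1 (malignant) throughout.
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

DEFAULT_BOX_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (0.01, 0.1, 1.0, 10.0)


def _validate_xy(X, y=None):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D [n_cases, n_features]")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if y is None:
        return X
    y = np.asarray(y)
    if set(np.unique(y)) - {-1, 1}:
        raise ValueError("labels must be -1 (benign) or +1 (malignant)")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return X, y.astype(int)


class _StandardizedScorer(BaseEstimator, ClassifierMixin):
    """Shared machinery: per-feature standardization frozen at fit time."""

    def _standardize_fit(self, X):
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        zero = self.scale_ <= 0
        if np.any(zero):
            idx = np.flatnonzero(zero)
            raise ValueError(f"zero-variance feature(s) at column(s) {idx.tolist()}")
        return (X - self.mean_) / self.scale_

    def _standardize(self, X):
        X = _validate_xy(X)
        return (X - self.mean_) / self.scale_

    @property
    def classes_(self):
        return np.array([-1, 1])

    def predict(self, X):
        d = self.decision_function(X)
        return np.where(d >= self.threshold_, 1, -1)


class PC1Scorer(_StandardizedScorer):
    """First-principal-component combined score.

    Attributes (after fit): ``loadings_`` (unit PC1 vector),
    ``contributions_`` (normalized absolute loadings, summing to 1),
    ``explained_variance_ratio_``.
    """

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        Z = self._standardize_fit(X)
        if Z.shape[0] < Z.shape[1]:
            raise ValueError("need at least as many cases as features for PCA")
        cov = np.cov(Z, rowvar=False)
        cov = np.atleast_2d(cov)
        evals, evecs = np.linalg.eigh(cov)
        if evals[-1] <= 0:
            raise ValueError("degenerate (rank-deficient) feature table")
        w = evecs[:, -1]
        # orient so malignant-class mean score exceeds benign-class mean
        s = Z @ w
        if s[y == 1].mean() < s[y == -1].mean():
            w = -w
            s = -s
        self.loadings_ = w
        self.contributions_ = np.abs(w) / np.abs(w).sum()
        self.explained_variance_ratio_ = float(evals[-1] / evals.sum())
        self.threshold_ = 0.5 * (s[y == 1].mean() + s[y == -1].mean())
        return self

    def decision_function(self, X):
        return self._standardize(X) @ self.loadings_


class ProjectionScorer(_StandardizedScorer):
    """Inner product with the standardized benign->malignant centroid direction."""

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        Z = self._standardize_fit(X)
        direction = Z[y == 1].mean(axis=0) - Z[y == -1].mean(axis=0)
        norm = np.linalg.norm(direction)
        if norm == 0:
            raise ValueError("class centroids coincide; reference direction undefined")
        self.reference_direction_ = direction / norm
        s = Z @ self.reference_direction_
        self.threshold_ = 0.5 * (s[y == 1].mean() + s[y == -1].mean())
        return self

    def decision_function(self, X):
        return self._standardize(X) @ self.reference_direction_


class SVMDistanceScorer(_StandardizedScorer):
    """Signed distance to a Gaussian-kernel SVM hyperplane.

    ``(box, gamma)`` are chosen by seeded 5-fold cross-validated accuracy on
    a grid; ties prefer the smaller box then the smaller gamma (the smoother
    hyperplane). The decision surface lives in standardized feature space.
    """

    def __init__(
        self,
        box_grid=DEFAULT_BOX_GRID,
        gamma_grid=DEFAULT_GAMMA_GRID,
        n_folds: int = 5,
        seed: int = 0,
    ):
        self.box_grid = box_grid
        self.gamma_grid = gamma_grid
        self.n_folds = n_folds
        self.seed = seed

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        Z = self._standardize_fit(X)
        n_folds = min(self.n_folds, int(np.bincount((y + 1) // 2).min()))
        if n_folds >= 2:
            cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=self.seed)
            best = None
            for box in sorted(self.box_grid):
                for gamma in sorted(self.gamma_grid):
                    accs = []
                    for tr, te in cv.split(Z, y):
                        clf = SVC(C=box, gamma=gamma, kernel="rbf")
                        clf.fit(Z[tr], y[tr])
                        accs.append(np.mean(clf.predict(Z[te]) == y[te]))
                    acc = float(np.mean(accs))
                    # strict > keeps the earlier (smaller box, then gamma) tie-winner
                    if best is None or acc > best[0]:
                        best = (acc, box, gamma)
            self.cv_accuracy_, self.box_, self.gamma_ = best
        else:  # tiny data: fall back to mid-grid defaults
            self.cv_accuracy_, self.box_, self.gamma_ = float("nan"), 1.0, 0.1
        svm = SVC(C=self.box_, gamma=self.gamma_, kernel="rbf")
        svm.fit(Z, y)
        # frozen as plain arrays so the decision function is serializable
        self.support_vectors_ = svm.support_vectors_.copy()
        self.dual_coef_ = svm.dual_coef_[0].copy()
        self.intercept_ = float(svm.intercept_[0])
        self.threshold_ = 0.0
        return self

    def _decision_standardized(self, Z):
        Z = np.atleast_2d(Z)
        d2 = (
            np.sum(Z**2, axis=1)[:, None]
            - 2.0 * Z @ self.support_vectors_.T
            + np.sum(self.support_vectors_**2, axis=1)[None, :]
        )
        k = np.exp(-self.gamma_ * np.maximum(d2, 0.0))
        return k @ self.dual_coef_ + self.intercept_

    def decision_function(self, X):
        return self._decision_standardized(self._standardize(X))

    def geometric_distance(self, X, max_iter: int = 200) -> np.ndarray:
        """Signed Euclidean distance (standardized space) to the decision surface.

        For each point, a zero crossing of the decision value is bracketed
        along the straight line toward the mean of opposite-sign support
        vectors, bisected, then refined by constrained minimization of the
        distance subject to f(z) = 0.
        """
        Z = self._standardize(X)
        f = self._decision_standardized(Z)
        out = np.zeros(len(Z))
        for i, (z, fz) in enumerate(zip(Z, f)):
            if fz == 0:
                continue
            out[i] = np.sign(fz) * self._surface_distance(z, fz, max_iter)
        return out

    def _surface_distance(self, z, fz, max_iter):
        sv_vals = self._decision_standardized(self.support_vectors_)
        opposite = self.support_vectors_[np.sign(sv_vals) != np.sign(fz)]
        if len(opposite) == 0:
            targets = [self.support_vectors_.mean(axis=0)]
        else:
            targets = [opposite.mean(axis=0), *opposite[:5]]
        best = np.inf
        for target in targets:
            zc = self._bisect_zero(z, fz, target, max_iter)
            if zc is None:
                continue
            res = minimize(
                lambda p: np.linalg.norm(p - z),
                zc,
                method="SLSQP",
                constraints=[{
                    "type": "eq",
                    "fun": lambda p: self._decision_standardized(p[None, :])[0],
                }],
                options={"maxiter": max_iter, "ftol": 1e-10},
            )
            cand = res.x if res.success else zc
            if abs(self._decision_standardized(cand[None, :])[0]) < 1e-6:
                best = min(best, float(np.linalg.norm(cand - z)))
            else:
                best = min(best, float(np.linalg.norm(zc - z)))
        if not np.isfinite(best):
            raise RuntimeError("could not bracket the decision surface")
        return best

    def _bisect_zero(self, z, fz, target, max_iter):
        direction = target - z
        if np.linalg.norm(direction) == 0:
            return None
        lo, hi = 0.0, 1.0
        f_hi = self._decision_standardized((z + hi * direction)[None, :])[0]
        expand = 0
        while np.sign(f_hi) == np.sign(fz) and expand < 20:
            hi *= 1.6
            f_hi = self._decision_standardized((z + hi * direction)[None, :])[0]
            expand += 1
        if np.sign(f_hi) == np.sign(fz):
            return None
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            f_mid = self._decision_standardized((z + mid * direction)[None, :])[0]
            if np.sign(f_mid) == np.sign(fz):
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-12:
                break
        return z + 0.5 * (lo + hi) * direction


class DSIModel(BaseEstimator, ClassifierMixin):
    """Trained multiparametric model: the three combiners plus clip limits.

    Parameters
    ----------
    combiner : {"pc1", "projection", "svm_distance"}
        Score exposed through ``decision_function`` / ``predict``.
    clip_percentiles : (lo, hi)
        Training-score percentiles used as clipping limits when mapping a
        score to a probability of malignancy.
    """

    def __init__(
        self,
        feature_names=None,
        combiner: str = "svm_distance",
        clip_percentiles=(5.0, 95.0),
        box_grid=DEFAULT_BOX_GRID,
        gamma_grid=DEFAULT_GAMMA_GRID,
        seed: int = 0,
    ):
        self.feature_names = feature_names
        self.combiner = combiner
        self.clip_percentiles = clip_percentiles
        self.box_grid = box_grid
        self.gamma_grid = gamma_grid
        self.seed = seed

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns) if self.feature_names is None else list(self.feature_names)
            X = X[names].to_numpy(dtype=float)
        else:
            names = (
                list(self.feature_names)
                if self.feature_names is not None
                else [f"f{i}" for i in range(np.asarray(X).shape[1])]
            )
        X, y = _validate_xy(X, y)
        self.feature_names_ = names
        self.scorers_ = {
            "pc1": PC1Scorer().fit(X, y),
            "projection": ProjectionScorer().fit(X, y),
            "svm_distance": SVMDistanceScorer(
                box_grid=self.box_grid, gamma_grid=self.gamma_grid, seed=self.seed
            ).fit(X, y),
        }
        lo, hi = self.clip_percentiles
        self.distance_limits_ = {
            name: tuple(np.percentile(sc.decision_function(X), [lo, hi]))
            for name, sc in self.scorers_.items()
        }
        self.contributions_ = dict(
            zip(self.feature_names_, self.scorers_["pc1"].contributions_)
        )
        return self

    def _as_array(self, X):
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names_].to_numpy(dtype=float)
        return X

    def decision_function(self, X, combiner: str | None = None):
        name = combiner or self.combiner
        if name not in self.scorers_:
            raise ValueError(f"unknown combiner {name!r}")
        return self.scorers_[name].decision_function(self._as_array(X))

    def score_triplet(self, X) -> pd.DataFrame:
        """All three combined scores per case."""
        X = self._as_array(X)
        return pd.DataFrame(
            {name: sc.decision_function(X) for name, sc in self.scorers_.items()}
        )

    def predict(self, X):
        name = self.combiner
        return self.scorers_[name].predict(self._as_array(X))

    @property
    def classes_(self):
        return np.array([-1, 1])

    # ---- JSON serialization -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        svm = self.scorers_["svm_distance"]
        pc1 = self.scorers_["pc1"]
        proj = self.scorers_["projection"]
        doc = {
            "schema": "echodsi-model/1",
            "feature_names": self.feature_names_,
            "combiner": self.combiner,
            "standardization": {
                name: {"mean": sc.mean_.tolist(), "scale": sc.scale_.tolist()}
                for name, sc in self.scorers_.items()
            },
            "pc1": {
                "loadings": pc1.loadings_.tolist(),
                "contributions": pc1.contributions_.tolist(),
                "explained_variance_ratio": pc1.explained_variance_ratio_,
                "threshold": pc1.threshold_,
            },
            "projection": {
                "reference_direction": proj.reference_direction_.tolist(),
                "threshold": proj.threshold_,
            },
            "svm": {
                "box": svm.box_,
                "gamma": svm.gamma_,
                "support_vectors": svm.support_vectors_.tolist(),
                "dual_coef": svm.dual_coef_.tolist(),
                "intercept": svm.intercept_,
            },
            "distance_limits": {k: list(v) for k, v in self.distance_limits_.items()},
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "DSIModel":
        text = str(source)
        if not text.lstrip().startswith("{"):  # a path, not a JSON document
            text = Path(source).read_text()
        doc = json.loads(text)
        model = cls(feature_names=doc["feature_names"], combiner=doc["combiner"])
        model.feature_names_ = doc["feature_names"]

        pc1 = PC1Scorer()
        pc1.loadings_ = np.array(doc["pc1"]["loadings"])
        pc1.contributions_ = np.array(doc["pc1"]["contributions"])
        pc1.explained_variance_ratio_ = doc["pc1"]["explained_variance_ratio"]
        pc1.threshold_ = doc["pc1"]["threshold"]

        proj = ProjectionScorer()
        proj.reference_direction_ = np.array(doc["projection"]["reference_direction"])
        proj.threshold_ = doc["projection"]["threshold"]

        svm = SVMDistanceScorer()
        svm.box_ = doc["svm"]["box"]
        svm.gamma_ = doc["svm"]["gamma"]
        svm.support_vectors_ = np.array(doc["svm"]["support_vectors"])
        svm.dual_coef_ = np.array(doc["svm"]["dual_coef"])
        svm.intercept_ = doc["svm"]["intercept"]
        svm.threshold_ = 0.0

        for name, sc in (("pc1", pc1), ("projection", proj), ("svm_distance", svm)):
            sc.mean_ = np.array(doc["standardization"][name]["mean"])
            sc.scale_ = np.array(doc["standardization"][name]["scale"])
        model.scorers_ = {"pc1": pc1, "projection": proj, "svm_distance": svm}
        model.distance_limits_ = {k: tuple(v) for k, v in doc["distance_limits"].items()}
        model.contributions_ = dict(zip(model.feature_names_, pc1.contributions_))
        return model


# ---- thin functional wrappers ----------------------------------------------

def fit_standardizer(features: pd.DataFrame):
    """(mean, std) per feature plus the standardized table (training freeze)."""
    X = features.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two rows")
    mu, sigma = X.mean(axis=0), X.std(axis=0)
    zero = sigma <= 0
    if np.any(zero):
        bad = [features.columns[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"zero-variance feature(s): {bad}")
    return mu, sigma, pd.DataFrame((X - mu) / sigma, columns=features.columns)


def fit_pc1(standardized: pd.DataFrame, labels) -> PC1Scorer:
    """PC1 of an (already roughly standardized) table; returns the estimator."""
    return PC1Scorer().fit(standardized.to_numpy(dtype=float), labels)


def projection_score(x, reference_direction) -> np.ndarray:
    """Inner product of standardized feature vectors with a unit reference."""
    u = np.asarray(reference_direction, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("zero reference direction")
    if not np.isclose(norm, 1.0, atol=1e-8):
        raise ValueError("reference direction must be a unit vector")
    return np.atleast_2d(np.asarray(x, dtype=float)) @ u


def train_svm(standardized, labels, box_grid=DEFAULT_BOX_GRID,
              gamma_grid=DEFAULT_GAMMA_GRID, seed: int = 0) -> SVMDistanceScorer:
    X = standardized.to_numpy(dtype=float) if hasattr(standardized, "to_numpy") else standardized
    return SVMDistanceScorer(box_grid=box_grid, gamma_grid=gamma_grid, seed=seed).fit(
        X, labels
    )


def svm_distance(model: SVMDistanceScorer, x, mode: str = "decision") -> np.ndarray:
    if not hasattr(model, "support_vectors_"):
        raise ValueError("model is not trained")
    if mode == "decision":
        return model.decision_function(np.atleast_2d(x))
    if mode == "geometric":
        return model.geometric_distance(np.atleast_2d(x))
    raise ValueError(f"unknown mode {mode!r}")


def select_features(
    features: pd.DataFrame,
    labels,
    scorer: str = "pc1",
    candidates: list[str] | None = None,
) -> dict:
    """Exhaustive in-sample AUC search over all nonempty feature subsets.

    Ties prefer smaller subsets, then lexicographic order. With the nine
    default candidates this enumerates 2^9 - 1 = 511 subsets.
    """
    if scorer not in ("pc1", "svm_distance"):
        raise ValueError("scorer must be 'pc1' or 'svm_distance'")
    names = list(candidates) if candidates is not None else list(features.columns)
    if len(names) < 2:
        raise ValueError("need at least two candidate features")
    y = np.asarray(labels)
    results = []
    for k in range(1, len(names) + 1):
        for subset in itertools.combinations(sorted(names), k):
            X = features[list(subset)].to_numpy(dtype=float)
            try:
                if scorer == "pc1":
                    if X.shape[1] == 1:
                        s = X[:, 0]
                        if s[y == 1].mean() < s[y == -1].mean():
                            s = -s
                    else:
                        s = PC1Scorer().fit(X, y).decision_function(X)
                else:
                    Z = (X - X.mean(axis=0)) / X.std(axis=0)
                    clf = SVC(C=1.0, gamma="scale", kernel="rbf").fit(Z, y)
                    s = clf.decision_function(Z)
                auc = roc_auc_score((y + 1) // 2, s)
            except (ValueError, np.linalg.LinAlgError):
                continue
            results.append({"subset": subset, "auc": auc})
    # max AUC; ties -> smaller subset, then lexicographic (iteration order)
    best = max(results, key=lambda r: r["auc"])
    return {
        "best_subset": list(best["subset"]),
        "best_auc": float(best["auc"]),
        "n_subsets": len(results),
        "table": results,
    }
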