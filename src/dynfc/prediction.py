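"""Ridge-regression prediction of model outcomes from FC features.

For each of the eight outcomes (four parameters, four fits) and each
feature family (sFC edges, TC nodes) a pipeline of standardisation, PCA,
and ridge regression is evaluated with nested cross-validation: the inner
loop picks the ridge penalty from 100 log-spaced values in [0.01, 100], the
outer loop estimates the coefficient-of-determination R^2 on held-out folds
(5 folds x 2 repeats, so the reported score is the mean of 10 evaluations;
it can be negative, i.e. worse than predicting the mean).  Edge models
reduce dimensionality to the minimal number of principal components
explaining more than 90 % of the training-set variance; node models keep
all components.

Feature importance permutes one *original* (pre-PCA) column at a time
through the frozen full-data pipeline and reports the mean R^2 drop; edge
importances are additionally averaged over each region's incident edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge
from sklearn.metrics import r2_score
from sklearn.model_selection import RepeatedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .association import FeatureTable

__all__ = [
    "PredictionSpec",
    "PredictionResult",
    "VarianceThresholdPCA",
    "ridge_nested_cv",
    "permutation_importance",
]


class VarianceThresholdPCA(TransformerMixin, BaseEstimator):
    """PCA keeping the minimal k with cumulative explained variance > threshold.

    ``threshold=None`` keeps all components.  Fit on training data only, so
    nested CV estimates the transform per training split.
    """

    def __init__(self, threshold: Optional[float] = 0.90):
        self.threshold = threshold

    def fit(self, X, y=None):
        self.pca_ = PCA(svd_solver="full")
        self.pca_.fit(X)
        if self.threshold is None:
            self.n_components_ = self.pca_.n_components_
        else:
            cum = np.cumsum(self.pca_.explained_variance_ratio_)
            self.n_components_ = int(np.searchsorted(cum, self.threshold, side="right")) + 1
            self.n_components_ = min(self.n_components_, self.pca_.n_components_)
        return self

    def transform(self, X):
        return self.pca_.transform(X)[:, : self.n_components_]


@dataclass(frozen=True)
class PredictionSpec:
    """Configuration of one prediction model."""

    feature_kind: str = "edge_sfc"
    target: str = "r_sfc"
    pca_variance: Optional[float] = 0.90
    alpha_grid: tuple[float, ...] = tuple(np.logspace(-2, 2, 100))
    outer_folds: int = 5
    outer_repeats: int = 2
    inner_folds: int = 5
    inner_repeats: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.alpha_grid) != sorted(self.alpha_grid):
            raise ValueError("alpha_grid must be sorted ascending")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass(frozen=True)
class PredictionResult:
    """Nested-CV score and (optionally) per-feature importance."""

    r2_mean: float
    r2_sem: float
    r2_scores: np.ndarray
    best_alpha: float
    per_feature_importance: Optional[np.ndarray] = None
    region_importance: Optional[np.ndarray] = None


def _make_pipeline(spec: PredictionSpec, alpha: float = 1.0) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("pca", VarianceThresholdPCA(threshold=spec.pca_variance)),
            ("ridge", Ridge(alpha=alpha)),
        ]
    )


def _select_alpha(X: np.ndarray, y: np.ndarray, spec: PredictionSpec, seed: int) -> float:
    """Inner CV: penalty with the best mean held-out R^2 (ties -> smaller)."""
    # held-out folds need >= 2 samples for a defined R^2
    n_splits = min(spec.inner_folds, max(2, X.shape[0] // 2))
    inner_cv = RepeatedKFold(
        n_splits=n_splits, n_repeats=spec.inner_repeats, random_state=seed
    )
    alphas = np.asarray(spec.alpha_grid)
    scores = np.zeros(alphas.size)
    for tr, te in inner_cv.split(X):
        pre = Pipeline(
            [
                ("scale", StandardScaler()),
                ("pca", VarianceThresholdPCA(threshold=spec.pca_variance)),
            ]
        ).fit(X[tr])
        Ztr, Zte = pre.transform(X[tr]), pre.transform(X[te])
        # whole ridge path in one SVD: PCA scores are train-centred, so the
        # intercept is exactly mean(y_train) and coef(a) = V s/(s^2+a) U'y
        ymean = y[tr].mean()
        U, s, Vt = np.linalg.svd(Ztr, full_matrices=False)
        Uty = U.T @ (y[tr] - ymean)
        shrink = s[:, None] / (s[:, None] ** 2 + alphas[None, :])
        W = Vt.T @ (shrink * Uty[:, None])  # (k, n_alpha)
        preds = Zte @ W + ymean
        yte = y[te]
        sst = ((yte - yte.mean()) ** 2).sum()
        if sst == 0:  # constant held-out fold: R^2 undefined, skip
            continue
        sse = ((yte[:, None] - preds) ** 2).sum(axis=0)
        scores += 1.0 - sse / sst
    return float(alphas[int(np.argmax(scores))])


def _fit_best(X: np.ndarray, y: np.ndarray, spec: PredictionSpec, seed: int) -> tuple[Pipeline, float]:
    alpha = _select_alpha(X, y, spec, seed)
    model = _make_pipeline(spec, alpha=alpha).fit(X, y)
    return model, alpha


def ridge_nested_cv(
    features: FeatureTable, target: np.ndarray, spec: PredictionSpec | None = None
) -> PredictionResult:
    """Nested-CV generalisation estimate for one outcome.

    Standardisation and PCA are fit inside each training portion only (no
    information leak); the outer R^2 is 1 - SSE/SST on the held-out fold.
    Deterministic given ``spec.seed``; outer and inner shuffles use disjoint
    derived seeds.
    """
    spec = spec or PredictionSpec()
    X = features.values
    y = np.asarray(target, float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and target disagree on subject count")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 subjects for nested CV")
    if y.std() == 0:
        raise ValueError("degenerate target: zero variance")
    outer_cv = RepeatedKFold(
        n_splits=spec.outer_folds, n_repeats=spec.outer_repeats, random_state=spec.seed
    )
    scores = []
    for train, test in outer_cv.split(X):
        if np.ptp(y[test]) == 0:  # constant held-out fold: R^2 undefined
            continue
        model, _ = _fit_best(X[train], y[train], spec, seed=spec.seed + 1)
        scores.append(r2_score(y[test], model.predict(X[test])))
    scores = np.asarray(scores)
    sem = scores.std(ddof=1) / np.sqrt(len(scores))
    # representative penalty: the inner winner on the full data
    full_alpha = _select_alpha(X, y, spec, seed=spec.seed + 1)
    return PredictionResult(
        r2_mean=float(scores.mean()),
        r2_sem=float(sem),
        r2_scores=scores,
        best_alpha=full_alpha,
    )


def _edge_incidence(labels: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray, int]:
    pairs = [tuple(int(t) for t in lab.split("_")[1:]) for lab in labels]
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    return ii, jj, int(max(ii.max(), jj.max())) + 1


def permutation_importance(
    features: FeatureTable,
    target: np.ndarray,
    spec: PredictionSpec | None = None,
    n_perm: int = 1000,
) -> PredictionResult:
    """Permutation importance of every original feature on the full data.

    The pipeline (standardise, PCA, ridge) is re-trained on the entire data
    set with the inner-CV-selected penalty and then frozen; each original
    column is shuffled ``n_perm`` times and the importance is the mean drop
    in full-data R^2.  The frozen pipeline is linear in X, so a permuted
    column f changes predictions by beta_f * (x_f[perm] - x_f), which the
    implementation exploits; beta is read off the pipeline by probing unit
    feature offsets.  Edge models also report per-region importance (mean
    over the region's incident edges).
    """
    spec = spec or PredictionSpec()
    X = features.values
    y = np.asarray(target, float)
    model, best_alpha = _fit_best(X, y, spec, seed=spec.seed + 1)
    yhat = model.predict(X)
    base_r2 = r2_score(y, yhat)

    # Linear composition: predict(X0 + e_f) - predict(X0) = beta_f.
    x0 = X.mean(axis=0, keepdims=True)
    probe = np.vstack([x0, x0 + np.eye(X.shape[1])])
    pred = model.predict(probe)
    beta = pred[1:] - pred[0]

    rng = np.random.default_rng(spec.seed + 2)
    m = X.shape[1]
    importance = np.empty(m)
    for f in range(m):
        xf = X[:, f]
        drops = np.empty(n_perm)
        for k in range(n_perm):
            delta = beta[f] * (xf[rng.permutation(len(xf))] - xf)
            drops[k] = base_r2 - r2_score(y, yhat + delta)
        importance[f] = drops.mean()

    region_importance = None
    if features.kind == "edge_sfc":
        ii, jj, n = _edge_incidence(features.labels)
        sums = np.zeros(n)
        counts = np.zeros(n)
        np.add.at(sums, ii, importance)
        np.add.at(counts, ii, 1)
        np.add.at(sums, jj, importance)
        np.add.at(counts, jj, 1)
        region_importance = sums / np.maximum(counts, 1)

    outer = ridge_nested_cv(features, y, spec)
    return PredictionResult(
        r2_mean=outer.r2_mean,
        r2_sem=outer.r2_sem,
        r2_scores=outer.r2_scores,
        best_alpha=best_alpha,
        per_feature_importance=importance,
        region_importance=region_importance,
    )
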