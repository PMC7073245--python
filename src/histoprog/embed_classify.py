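"""Low-dimensional visualization and cross-validated tumor/normal classification.

Visualization follows the standard two-step recipe for high-dimensional CNN
features: PCA down to 10 components, then Barnes-Hut t-SNE (perplexity 15)
to 2 dimensions. Classification uses a linear maximum-margin classifier
(C = 1) under stratified 6-fold cross-validation, with per-fold ROC AUC and
average precision pooled over out-of-fold decision scores. Features are
standardized with train-fold statistics before the margin fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import LabelError, ParameterError

__all__ = ["ClassificationReport", "embed", "classify_cv", "feature_subset_experiment"]


def _as_matrix(features) -> np.ndarray:
    if hasattr(features, "values") and isinstance(features.values, pd.DataFrame):
        return features.values.to_numpy(float)
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(float)
    return np.asarray(features, float)


@dataclass
class ClassificationReport:
    fold_aucs: list = field(default_factory=list)
    mean_auc: float = float("nan")
    average_precision: float = float("nan")
    fold_count: int = 0
    regularization_c: float = 1.0

    def to_dict(self) -> dict:
        return {
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "mean_auc": float(self.mean_auc),
            "average_precision": float(self.average_precision),
            "fold_count": self.fold_count,
            "regularization_c": self.regularization_c,
        }


def embed(
    features,
    n_components: int = 10,
    perplexity: float = 15.0,
    seed: int = 0,
) -> np.ndarray:
    """PCA to ``n_components`` followed by seeded Barnes-Hut t-SNE to 2-D."""
    X = _as_matrix(features)
    n, p = X.shape
    if n_components > min(n, p):
        raise ParameterError(f"n_components {n_components} > min(samples, features)")
    if perplexity >= (n - 1) / 3:
        raise ParameterError(
            f"perplexity {perplexity} too large for {n} samples (need < (n-1)/3)"
        )
    pcs = PCA(n_components=n_components, svd_solver="auto", random_state=seed).fit_transform(X)
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        method="barnes_hut",
        random_state=seed,
        init="pca",
    )
    return ts.fit_transform(pcs)


def classify_cv(
    features,
    labels,
    folds: int = 6,
    c: float = 1.0,
    seed: int = 0,
) -> ClassificationReport:
    """Stratified k-fold linear-SVM classification with ROC/AUC and AP.

    Returns per-fold held-out AUCs, their mean, and average precision from
    the pooled out-of-fold decision scores.
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise LabelError(f"need exactly 2 classes, got {list(classes)}")
    if counts.min() < folds:
        raise LabelError(
            f"minority class has {counts.min()} members; need >= folds ({folds})"
        )
    # Positive class: 'tumor' when present, else the lexicographically larger.
    positive = "tumor" if "tumor" in classes else classes[-1]
    y_bin = (y == positive).astype(int)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs = []
    pooled_scores = np.empty(len(y), float)
    for train, test in skf.split(X, y_bin):
        scaler = StandardScaler().fit(X[train])
        clf = SVC(kernel="linear", C=c)
        clf.fit(scaler.transform(X[train]), y_bin[train])
        scores = clf.decision_function(scaler.transform(X[test]))
        pooled_scores[test] = scores
        fold_aucs.append(float(roc_auc_score(y_bin[test], scores)))
    return ClassificationReport(
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)),
        average_precision=float(average_precision_score(y_bin, pooled_scores)),
        fold_count=folds,
        regularization_c=c,
    )


def feature_subset_experiment(
    features,
    labels,
    sizes=(10, 25, 50, 100),
    repeats: int = 5,
    folds: int = 6,
    c: float = 1.0,
    seed: int = 0,
) -> dict:
    """Mean cross-validated AUC over random feature subsets of each size."""
    X = _as_matrix(features)
    p = X.shape[1]
    if max(sizes) > p:
        raise ParameterError(f"max subset size {max(sizes)} exceeds {p} features")
    rng = np.random.default_rng(seed)
    out = {}
    for size in sizes:
        aucs = []
        for _ in range(repeats):
            cols = rng.choice(p, size=size, replace=False)
            rep = classify_cv(X[:, cols], labels, folds=folds, c=c, seed=seed)
            aucs.append(rep.mean_auc)
        out[int(size)] = float(np.mean(aucs))
    return out
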