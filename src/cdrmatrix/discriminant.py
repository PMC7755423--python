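"""Class discrimination: frequency differences, PCA, LDA and the SVM classifier.

Two modes of linear discriminant use are supported, mirroring how repertoire
comparisons are usually run:

* mode 1 ("separation"): fit on all sequences after reducing the feature
  space, report the projection and the fraction of sequences falling on the
  correct side of the midpoint between the projected class means, and map the
  discriminant weights back to (property, column) names;
* mode 2 ("classification"): a linear-kernel SVM evaluated with leave-one-out
  cross-validation, where standardization and feature selection are refit
  inside every fold so no information leaks from the held-out sequence.

Feature selection ranks z-scored columns by the absolute difference of class
means, after greedily discarding the lower-ranked member of any pair of
columns correlated above a threshold.  A scrambled-label control re-runs the
classifier under random labels; balanced classes should score near 50%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.model_selection import LeaveOneOut
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .property_masks import FeatureMatrix, standardize_columns
from .sequence_io import (
    NONSTANDARD_CODE,
    EncodedMatrix,
    decode_code,
    ordered_class_labels,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# residue frequency differences (encoded-matrix view)

@dataclass
class FrequencyDifferenceMap:
    """Per (column, residue code) difference of within-class frequencies."""

    delta: np.ndarray          # L x 21, code index 1..21 in column dimension
    label_a: str
    label_b: str
    display_threshold: float

    @property
    def filtered(self) -> np.ndarray:
        out = self.delta.copy()
        out[np.abs(out) <= self.display_threshold] = 0.0
        return out

    def to_frame(self) -> pd.DataFrame:
        codes = range(1, NONSTANDARD_CODE + 1)
        return pd.DataFrame(
            self.delta,
            columns=[decode_code(c) for c in codes],
            index=pd.Index(range(self.delta.shape[0]), name="column"),
        )


def aa_frequency_difference(
    matrix: EncodedMatrix,
    display_threshold: float = 0.10,
) -> FrequencyDifferenceMap:
    """Frequency of each residue code per column, differenced between classes.

    Positive entries mark residues more common in the first class label
    (polyreactive when present).  ``filtered`` zeroes |delta| <= threshold
    for display.
    """
    label_a, label_b = ordered_class_labels(matrix.row_labels)
    arr = np.asarray(matrix.row_labels)
    rows_a = matrix.values[arr == label_a]
    rows_b = matrix.values[arr == label_b]
    if rows_a.shape[0] == 0 or rows_b.shape[0] == 0:
        raise ValueError("empty class")
    L = matrix.values.shape[1]
    delta = np.zeros((L, NONSTANDARD_CODE))
    for code in range(1, NONSTANDARD_CODE + 1):
        fa = (rows_a == code).mean(axis=0)
        fb = (rows_b == code).mean(axis=0)
        delta[:, code - 1] = fa - fb
    return FrequencyDifferenceMap(
        delta=delta, label_a=label_a, label_b=label_b,
        display_threshold=display_threshold,
    )


# ---------------------------------------------------------------------------
# PCA

def pca_project(
    features: FeatureMatrix | np.ndarray,
    n_components: int = 2,
) -> tuple[np.ndarray, np.ndarray, PCA]:
    """PCA on z-scored features; returns (projections, explained ratio, model).

    Component signs are fixed by making each component's largest-magnitude
    loading positive, so results are deterministic across runs.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if X.shape[0] <= n_components:
        raise ValueError("need more rows than components")
    Xz, _, sds = standardize_columns(X)
    if np.all(sds == 0):
        raise ValueError("all features constant; PCA undefined")
    pca = PCA(n_components=n_components, svd_solver="full")
    proj = pca.fit_transform(Xz)
    for i, comp in enumerate(pca.components_):
        if comp[np.argmax(np.abs(comp))] < 0:
            pca.components_[i] = -comp
            proj[:, i] = -proj[:, i]
    return proj, pca.explained_variance_ratio_, pca


def pca_class_assignment(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    n_components: int = 2,
) -> np.ndarray:
    """Assign test rows to the nearest class centroid in PCA space.

    The PCA basis and column standardization come from the training rows only.
    """
    train_labels = np.asarray(train_labels)
    Xz, means, sds = standardize_columns(np.asarray(train_features, dtype=float))
    safe = np.where(sds > 0, sds, 1.0)
    pca = PCA(n_components=n_components, svd_solver="full")
    train_proj = pca.fit_transform(Xz)
    test_z = (np.asarray(test_features, dtype=float) - means) / safe
    test_z[:, sds == 0] = 0.0
    test_proj = pca.transform(test_z)
    classes = np.unique(train_labels)
    centroids = np.vstack([train_proj[train_labels == c].mean(axis=0) for c in classes])
    d = np.linalg.norm(test_proj[:, None, :] - centroids[None, :, :], axis=2)
    return classes[np.argmin(d, axis=1)]


# ---------------------------------------------------------------------------
# feature selection

def _rank_by_mean_difference(X: np.ndarray, y01: np.ndarray) -> np.ndarray:
    Xz, _, _ = standardize_columns(X)
    diff = np.abs(Xz[y01 == 1].mean(axis=0) - Xz[y01 == 0].mean(axis=0))
    return np.argsort(-diff, kind="stable")


def _greedy_correlation_filter(
    X: np.ndarray, ranked: np.ndarray, threshold: float, k: int
) -> list[int]:
    """Walk features in rank order, keeping those not correlated above
    ``threshold`` with any already-kept feature, until k are kept."""
    kept: list[int] = []
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc ** 2).sum(axis=0))
    for idx in ranked:
        if len(kept) >= k:
            break
        if norms[idx] == 0:
            continue  # constant column carries no signal
        if kept:
            r = (Xc[:, kept].T @ Xc[:, idx]) / (norms[kept] * norms[idx])
            if np.any(np.abs(r) > threshold):
                continue
        kept.append(int(idx))
    return kept


@dataclass
class SelectionResult:
    indices: list[int]
    names: list[str]
    method: str
    k: int
    correlation_threshold: float | None


def select_features(
    features: FeatureMatrix,
    labels: np.ndarray | None = None,
    method: str = "top_diff",
    k: int = 75,
    correlation_threshold: float = 0.75,
) -> tuple[np.ndarray, SelectionResult]:
    """Reduce the feature matrix before discriminant fitting.

    ``top_diff`` keeps the k columns with the largest absolute z-scored class
    mean difference, dropping the lower-ranked member of any pair with
    |Pearson r| above the threshold.  ``pca`` keeps the first k principal
    components instead.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    X = features.values
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds feature count {X.shape[1]}")
    if method == "pca":
        proj, _, _ = pca_project(features, n_components=min(k, X.shape[0] - 1))
        sel = SelectionResult(
            indices=list(range(proj.shape[1])),
            names=[f"PC{i + 1}" for i in range(proj.shape[1])],
            method="pca", k=k, correlation_threshold=None,
        )
        return proj, sel
    if method != "top_diff":
        raise ValueError(f"unknown selection method {method!r}")
    y = np.asarray(labels if labels is not None else features.row_labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("top_diff selection needs exactly two classes")
    y01 = (y == classes[1]).astype(int)
    ranked = _rank_by_mean_difference(X, y01)
    kept = _greedy_correlation_filter(X, ranked, correlation_threshold, k)
    sel = SelectionResult(
        indices=kept,
        names=[features.columns[i] for i in kept],
        method="top_diff", k=k, correlation_threshold=correlation_threshold,
    )
    return X[:, kept], sel


class TopDifferenceSelector(BaseEstimator, TransformerMixin):
    """Sklearn-compatible transformer wrapping the rank + correlation filter,
    so selection is refit inside every cross-validation fold."""

    def __init__(self, k: int = 75, correlation_threshold: float = 0.75):
        self.k = k
        self.correlation_threshold = correlation_threshold

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("needs exactly two classes")
        y01 = (y == classes[1]).astype(int)
        ranked = _rank_by_mean_difference(X, y01)
        self.indices_ = _greedy_correlation_filter(
            X, ranked, self.correlation_threshold, min(self.k, X.shape[1])
        )
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.indices_]


# ---------------------------------------------------------------------------
# LDA (mode 1)

@dataclass
class DiscriminantResult:
    weights: np.ndarray
    feature_names: list[str]
    projections: np.ndarray
    threshold: float
    accuracy: float
    label_positive: str
    label_negative: str
    ridge_epsilon: float | None = None

    def top_weights(self, k: int = 10) -> pd.DataFrame:
        order = np.argsort(-np.abs(self.weights))[:k]
        return pd.DataFrame({
            "feature": [self.feature_names[i] for i in order],
            "weight": self.weights[order],
        })


def lda_fit_project(
    X: np.ndarray,
    labels: np.ndarray,
    feature_names: list[str] | None = None,
    ridge_epsilon: float = 1e-6,
) -> DiscriminantResult:
    """Two-class Fisher linear discriminant fit on all rows (mode 1).

    Maximizes between-class separation over within-class scatter; a ridge
    term stabilizes singular scatter matrices.  Separation accuracy is the
    fraction of rows on the correct side of the midpoint between the
    projected class means, with the axis oriented toward the second
    (alphabetically later) class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    neg, pos = classes[0], classes[1]
    Xn, Xp = X[y == neg], X[y == pos]
    if Xn.shape[0] < 2 or Xp.shape[0] < 2:
        raise ValueError("each class needs at least 2 rows")
    if X.shape[1] >= X.shape[0]:
        raise ValueError(
            f"feature count {X.shape[1]} >= sample count {X.shape[0]}: "
            "reduce features first (overfit guard)"
        )
    mu_n, mu_p = Xn.mean(axis=0), Xp.mean(axis=0)
    Sw = np.cov(Xn, rowvar=False) * (Xn.shape[0] - 1) + \
        np.cov(Xp, rowvar=False) * (Xp.shape[0] - 1)
    Sw = np.atleast_2d(Sw)
    eps_used = None
    try:
        w = np.linalg.solve(Sw, mu_p - mu_n)
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        eps_used = ridge_epsilon
        logger.info("singular within-class scatter; ridge epsilon %g applied", eps_used)
        w = np.linalg.solve(Sw + eps_used * np.eye(Sw.shape[0]), mu_p - mu_n)
    proj = X @ w
    mean_p, mean_n = proj[y == pos].mean(), proj[y == neg].mean()
    if mean_p < mean_n:  # orient toward the positive class
        w, proj = -w, -proj
        mean_p, mean_n = -mean_p, -mean_n
    threshold = 0.5 * (mean_p + mean_n)
    predicted = np.where(proj > threshold, pos, neg)
    accuracy = float((predicted == y).mean())
    names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    return DiscriminantResult(
        weights=w, feature_names=list(names), projections=proj,
        threshold=float(threshold), accuracy=accuracy,
        label_positive=str(pos), label_negative=str(neg),
        ridge_epsilon=eps_used,
    )


# ---------------------------------------------------------------------------
# SVM / LOOCV (mode 2)

@dataclass
class ClassifierReport:
    loocv_accuracy: float
    predictions: list[str]
    truth: list[str]
    k: int
    correlation_threshold: float
    standardize: bool
    seed: int | None
    scrambled_accuracy: float | None = None
    settings: dict = field(default_factory=dict)


def _loocv_pipeline(k: int, correlation_threshold: float, standardize: bool) -> Pipeline:
    steps = []
    if standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("select", TopDifferenceSelector(k=k, correlation_threshold=correlation_threshold)))
    steps.append(("svm", SVC(kernel="linear", C=1.0, class_weight="balanced")))
    return Pipeline(steps)


def svm_loocv(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    k: int = 75,
    correlation_threshold: float = 0.75,
    standardize: bool = True,
    seed: int | None = None,
) -> ClassifierReport:
    """Linear-kernel SVM accuracy under leave-one-out cross-validation.

    Standardization and top-difference feature selection are refit on the
    N-1 training rows of every fold, so the held-out sequence never informs
    its own feature set.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    y = np.asarray(labels if labels is not None else features.row_labels)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 sequences for LOOCV")
    k = min(k, X.shape[1])
    pipe = _loocv_pipeline(k, correlation_threshold, standardize)
    preds = []
    for train_idx, test_idx in LeaveOneOut().split(X):
        y_train = y[train_idx]
        if np.unique(y_train).size < 2:
            logger.warning("fold %d skipped: one class absent from training rows",
                           int(test_idx[0]))
            preds.append(None)
            continue
        pipe.fit(X[train_idx], y_train)
        preds.append(str(pipe.predict(X[test_idx])[0]))
    valid = [(p, t) for p, t in zip(preds, y) if p is not None]
    accuracy = float(np.mean([p == t for p, t in valid])) if valid else float("nan")
    return ClassifierReport(
        loocv_accuracy=accuracy,
        predictions=[p if p is not None else "" for p in preds],
        truth=[str(t) for t in y],
        k=k, correlation_threshold=correlation_threshold,
        standardize=standardize, seed=seed,
        settings={"kernel": "linear", "C": 1.0, "class_weight": "balanced"},
    )


def scrambled_control(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    repeats: int = 20,
    seed: int | None = None,
    k: int = 75,
    correlation_threshold: float = 0.75,
    standardize: bool = True,
) -> dict:
    """LOOCV accuracy distribution after random label assignment.

    With balanced classes the expectation is 50%; a real classifier should
    beat its scrambled control decisively.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    y = np.asarray(labels if labels is not None else features.row_labels)
    rng = np.random.default_rng(seed)
    accuracies = []
    for _ in range(repeats):
        y_perm = rng.permutation(y)
        rep = svm_loocv(
            X, y_perm, k=k, correlation_threshold=correlation_threshold,
            standardize=standardize,
        )
        accuracies.append(rep.loocv_accuracy)
    acc = np.asarray(accuracies)
    return {
        "accuracies": acc,
        "mean": float(acc.mean()),
        "sd": float(acc.std(ddof=1)) if repeats > 1 else 0.0,
        "repeats": repeats,
        "seed": seed,
    }
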