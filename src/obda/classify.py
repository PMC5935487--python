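"""Feature-based neuronal subtype classification.

Five variables distinguish the two subtypes (soma area, current threshold,
onset rapidness, input-output slope, maximum spike count).  Onset rapidness
is log-transformed, every column is z-scored, PCA summarises the
standardised matrix for reporting, and two-cluster k-means on the
standardised five-variable matrix assigns subtype labels, validated by a
leave-one-out protocol.

:class:`SubtypeClassifier` is a scikit-learn style estimator; the
:func:`pca_kmeans_classify` and helper functions below are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

FEATURE_COLUMNS = [
    "soma_area_um2",
    "current_threshold_pA_per_pF",
    "onset_rapidness_per_ms",
    "io_slope_hz_per_pA_per_pF",
    "max_spikes",
]
LOG_COLUMNS = ("onset_rapidness_per_ms",)
OUTLIER_Z = 3.0

__all__ = [
    "FEATURE_COLUMNS",
    "ClassificationResult",
    "SubtypeClassifier",
    "remove_outliers",
    "build_feature_matrix",
    "pca_kmeans_classify",
]


@dataclass
class ClassificationResult:
    scores: np.ndarray                 # (n, >=2) PC scores
    variance_fractions: np.ndarray     # all components; sums to 1
    labels: np.ndarray                 # aligned cluster labels in {0, 1}
    loo_accuracy: float


def remove_outliers(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop values with absolute z-score strictly above 3.

    z-scores use the sample mean and SD (n-1).  A zero-SD sample removes
    nothing.  Returns (kept values, removed indices).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("outlier removal needs at least two values")
    sd = np.std(x, ddof=1)
    if sd == 0:
        return x.copy(), np.empty(0, dtype=int)
    z = (x - np.mean(x)) / sd
    removed = np.flatnonzero(np.abs(z) > OUTLIER_Z)
    kept = np.delete(x, removed)
    return kept, removed


def build_feature_matrix(features: pd.DataFrame) -> np.ndarray:
    """Log-transform onset rapidness and z-score every column.

    Columns follow the fixed FEATURE_COLUMNS order.  Raises on incomplete
    rows, nonpositive onset rapidness, or a zero-variance column.
    """
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    mat = features[FEATURE_COLUMNS].to_numpy(dtype=float).copy()
    if not np.all(np.isfinite(mat)):
        raise ValueError("feature matrix must be complete and finite")
    for j, col in enumerate(FEATURE_COLUMNS):
        if col in LOG_COLUMNS:
            if np.any(mat[:, j] <= 0):
                raise ValueError(f"{col} must be positive for log transform")
            mat[:, j] = np.log10(mat[:, j])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if len(bad):
        raise ValueError(
            f"zero-variance columns: {[FEATURE_COLUMNS[j] for j in bad]}")
    return (mat - mean) / sd


def _align_labels(pred: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Relabel clusters so they majority-match the reference labels."""
    match = np.mean(pred == ref)
    return pred if match >= 0.5 else 1 - pred


class SubtypeClassifier(BaseEstimator):
    """PCA + two-cluster k-means subtype classifier.

    Parameters
    ----------
    n_init : int
        k-means restarts (deterministic given ``random_state``).
    random_state : int
        Seed for the k-means initialisation.
    standardize : bool
        Apply the log/z-score preprocessing of :func:`build_feature_matrix`.
        With raw units PC1 would simply track soma area's scale, so this
        defaults to True.

    Attributes (after ``fit``)
    --------------------------
    labels_ : aligned cluster labels in {0, 1}
    scores_ : PC scores of the standardised matrix
    explained_variance_ratio_ : variance fraction per component (sums to 1)
    cluster_centers_ : k-means centroids in standardised feature space
    loo_accuracy_ : leave-one-out accuracy against the reference labels
        (against the full-fit labels when none are given)
    """

    def __init__(self, n_init: int = 10, random_state: int = 0,
                 standardize: bool = True):
        self.n_init = n_init
        self.random_state = random_state
        self.standardize = standardize

    # -- helpers ----------------------------------------------------------

    def _prepare(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if self.standardize:
                return build_feature_matrix(X)
            return X[FEATURE_COLUMNS].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if self.standardize:
            return build_feature_matrix(
                pd.DataFrame(X, columns=FEATURE_COLUMNS))
        return X

    def _kmeans(self) -> KMeans:
        return KMeans(n_clusters=2, n_init=self.n_init,
                      random_state=self.random_state)

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y=None) -> "SubtypeClassifier":
        """Cluster the feature matrix and run leave-one-out validation.

        ``y`` (optional) are reference subtype labels in {0, 1} used for
        cluster alignment and LOO accuracy.
        """
        Xs = self._prepare(X)
        n = len(Xs)
        if n < 4:
            raise ValueError("need at least four rows")
        if np.linalg.matrix_rank(Xs) == 0:
            raise ValueError("degenerate (rank-0) feature matrix")

        pca = PCA(n_components=min(Xs.shape))
        scores = pca.fit_transform(Xs)

        km = self._kmeans().fit(Xs)
        labels = km.labels_.astype(int)
        ref = np.asarray(y, dtype=int) if y is not None else labels
        labels = _align_labels(labels, ref)

        # leave-one-out: refit on n-1 rows, assign the held-out row to the
        # nearest centroid, compare with the reference label
        correct = 0
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            km_i = self._kmeans().fit(Xs[mask])
            train_pred = _align_labels(km_i.labels_.astype(int), ref[mask])
            # map raw cluster ids to aligned labels via the training rows
            flip = not np.array_equal(train_pred, km_i.labels_)
            held = int(km_i.predict(Xs[i:i + 1])[0])
            if flip:
                held = 1 - held
            correct += held == ref[i]

        self.n_features_in_ = Xs.shape[1]
        self.mean_ = None
        self.pca_ = pca
        self.scores_ = scores
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.cluster_centers_ = km.cluster_centers_
        self.labels_ = labels
        self._raw_to_aligned_flip = not np.array_equal(
            labels, km.labels_.astype(int))
        self._km = km
        self.loo_accuracy_ = correct / n
        return self

    def predict(self, X) -> np.ndarray:
        """Assign new rows to the nearest fitted centroid."""
        Xs = self._prepare(X)
        raw = self._km.predict(Xs).astype(int)
        return 1 - raw if self._raw_to_aligned_flip else raw

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).labels_


def pca_kmeans_classify(features: pd.DataFrame | np.ndarray,
                        reference_labels: np.ndarray | None = None,
                        seed: int = 0) -> ClassificationResult:
    """Convenience wrapper around :class:`SubtypeClassifier`."""
    clf = SubtypeClassifier(random_state=seed).fit(features, reference_labels)
    return ClassificationResult(
        scores=clf.scores_,
        variance_fractions=clf.explained_variance_ratio_,
        labels=clf.labels_,
        loo_accuracy=clf.loo_accuracy_)
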