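"""Probabilistic binary classifiers over feature-function encodings.

Three classifiers are supported:

* kNN with a group-normalized l2 distance: each feature component is divided
  by its training-set standard deviation and each feature function's block is
  down-weighted by 1/d_g so that high-dimensional functions (a local PSSM
  window has hundreds of columns) do not dominate low-dimensional ones.  The
  predicted probability is the frequency of bonded pairs among the k nearest
  training samples.
* Extremely randomized trees (ETs): an ensemble of N fully developed trees;
  each leaf carries the empirical proportion of bonded pairs among its
  training samples and the ensemble output is the mean over trees.  Defaults:
  N = 1000, K = ceil(sqrt(D)) split candidates per node, Nmin = 2.
* RBF-kernel SVM with Platt-style probability calibration, operating in the
  same group-normalized feature space as the kNN distance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.svm import SVC

from .core import BondingProbabilityMatrix, Protein
from .features import FeatureFunctionSet, encode_pair

#: SVM hyper-parameter grids (powers of two, LibSVM practice)
SVM_C_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))
SVM_GAMMA_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))


class DegenerateModelWarning(UserWarning):
    pass


@dataclass
class FeatureScaler:
    """Per-component standard deviations grouped by feature function.

    The transform maps x to x_gk / (sigma_gk * sqrt(d_g)) so that the plain
    Euclidean norm of transformed differences equals the group-normalized
    distance.  Components with sigma = 0 are excluded (mapped to 0).
    """

    sigma: np.ndarray
    group_sizes: List[int]

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.ndim != 1 or np.any(self.sigma < 0):
            raise ValueError("sigma must be a non-negative vector")
        if sum(self.group_sizes) != self.sigma.shape[0]:
            raise ValueError("group sizes do not sum to the dimensionality")

    @classmethod
    def fit(cls, X: np.ndarray, group_sizes: Sequence[int]) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        return cls(sigma=X.std(axis=0), group_sizes=list(group_sizes))

    @property
    def n_features(self) -> int:
        return self.sigma.shape[0]

    @property
    def degenerate_components(self) -> np.ndarray:
        return np.flatnonzero(self.sigma == 0)

    def _weights(self) -> np.ndarray:
        inv = np.zeros_like(self.sigma)
        nonzero = self.sigma > 0
        inv[nonzero] = 1.0 / self.sigma[nonzero]
        d_g = np.concatenate(
            [np.full(d, d, dtype=float) for d in self.group_sizes]
        ) if self.group_sizes else np.zeros(0)
        return inv / np.sqrt(d_g)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        return X * self._weights()


def normalized_distance(
    x: np.ndarray, y: np.ndarray, scaler: FeatureScaler
) -> float:
    """Group-normalized l2 distance:

    sqrt( sum_g (1/d_g) sum_k ((x_gk - y_gk) / sigma_gk)^2 )

    with zero-variance components contributing 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.shape[0] != scaler.n_features:
        raise ValueError("x, y and scaler must share dimensionality")
    diff = scaler.transform(x) - scaler.transform(y)
    return float(np.linalg.norm(diff))


@dataclass
class ClassifierConfig:
    """Configuration for one of the three pair classifiers."""

    kind: str = "et"
    knn_k: int = 10
    svm_C: float = 1.0
    svm_gamma: float = 2.0 ** -3
    et_n_trees: int = 1000
    et_k: Optional[int] = None  # None -> ceil(sqrt(D)) at fit time
    et_nmin: int = 2

    def __post_init__(self):
        if self.kind not in ("knn", "svm", "et"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")

    @classmethod
    def knn(cls, k: int = 10) -> "ClassifierConfig":
        return cls(kind="knn", knn_k=k)

    @classmethod
    def svm(cls, C: float = 1.0, gamma: float = 2.0 ** -3) -> "ClassifierConfig":
        return cls(kind="svm", svm_C=C, svm_gamma=gamma)

    @classmethod
    def et(
        cls, n_trees: int = 1000, k: Optional[int] = None, nmin: int = 2
    ) -> "ClassifierConfig":
        return cls(kind="et", et_n_trees=n_trees, et_k=k, et_nmin=nmin)

    def with_trees(self, n_trees: int) -> "ClassifierConfig":
        return replace(self, et_n_trees=n_trees)


@dataclass
class TrainedPairClassifier:
    """A fitted classifier plus its scaler and feature-function set."""

    config: ClassifierConfig
    feature_set: FeatureFunctionSet
    scaler: FeatureScaler
    _model: object = None
    _train_X: Optional[np.ndarray] = None  # scaled, kNN only
    _train_y: Optional[np.ndarray] = None
    _constant: Optional[float] = None

    @property
    def n_features(self) -> int:
        return self.scaler.n_features

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Bonding probabilities for rows of ``X`` (raw feature space)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"classifier was trained on {self.n_features} features,"
                f" got {X.shape[1]}"
            )
        if self._constant is not None:
            return np.full(X.shape[0], self._constant)
        if self.config.kind == "knn":
            return np.array(
                [
                    knn_predict_proba(
                        row, self._train_X, self._train_y, self.config.knn_k,
                        pre_scaled=True, scaler=self.scaler,
                    )
                    for row in X
                ]
            )
        if self.config.kind == "svm":
            scores = self._model.predict_proba(self.scaler.transform(X))
        else:
            scores = self._model.predict_proba(X)
        positive = list(self._model.classes_).index(1)
        return scores[:, positive]


def knn_predict_proba(
    query: np.ndarray,
    train_X: np.ndarray,
    train_y: np.ndarray,
    k: int,
    scaler: Optional[FeatureScaler] = None,
    pre_scaled: bool = False,
) -> float:
    """Frequency of bonded pairs among the k nearest training samples.

    Distances use the group-normalized l2 norm; ties at the k-th distance are
    resolved by stable training order.  The possible outputs are the k+1
    values 0, 1/k, ..., 1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    train_X = np.asarray(train_X, dtype=float)
    if train_X.shape[0] < k:
        raise ValueError(
            f"kNN with k={k} needs at least {k} training samples,"
            f" got {train_X.shape[0]}"
        )
    query = np.asarray(query, dtype=float).ravel()
    if pre_scaled:
        q, T = query, train_X
    else:
        if scaler is None:
            raise ValueError("a scaler is required for unscaled inputs")
        q = scaler.transform(query)[0]
        T = scaler.transform(train_X)
    distances = np.linalg.norm(T - q, axis=1)
    order = np.argsort(distances, kind="stable")[:k]
    return float(np.mean(np.asarray(train_y)[order]))


def train_pair_classifier(
    X: np.ndarray,
    y: np.ndarray,
    feature_set: FeatureFunctionSet,
    config: ClassifierConfig,
    seed: int = 0,
    group_sizes: Optional[Sequence[int]] = None,
) -> TrainedPairClassifier:
    """Fit a pair classifier on labeled encodings; deterministic given seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one label per row")
    if group_sizes is None:
        group_sizes = feature_set.group_sizes
    scaler = FeatureScaler.fit(X, group_sizes)
    trained = TrainedPairClassifier(config=config, feature_set=feature_set, scaler=scaler)
    classes = np.unique(y)
    if classes.shape[0] < 2:
        warnings.warn(
            "single-class training set; returning a constant predictor",
            DegenerateModelWarning,
        )
        trained._constant = float(classes[0]) if classes.size else 0.0
        return trained
    if config.kind == "knn":
        trained._train_X = scaler.transform(X)
        trained._train_y = y
        if X.shape[0] < config.knn_k:
            raise ValueError(
                f"kNN with k={config.knn_k} needs at least {config.knn_k} samples"
            )
        return trained
    if config.kind == "svm":
        model = SVC(
            kernel="rbf",
            C=config.svm_C,
            gamma=config.svm_gamma,
            probability=True,
            random_state=seed,
        )
        model.fit(scaler.transform(X), y)
        trained._model = model
        return trained
    k = config.et_k or max(1, math.ceil(math.sqrt(X.shape[1])))
    model = ExtraTreesClassifier(
        n_estimators=config.et_n_trees,
        max_features=min(k, X.shape[1]),
        min_samples_split=config.et_nmin,
        bootstrap=False,  # each tree uses all learning samples
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X, y)
    trained._model = model
    return trained


def predict_pair_matrix(
    classifier: TrainedPairClassifier, protein: Protein
) -> BondingProbabilityMatrix:
    """Bonding probabilities for all n(n-1)/2 cysteine pairs of a protein."""
    n = protein.n_cys
    probs = np.zeros((n, n))
    if n < 2:
        return BondingProbabilityMatrix(probs)
    pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    X = np.vstack([encode_pair(protein, pair, classifier.feature_set) for pair in pairs])
    p = np.clip(classifier.predict_proba(X), 0.0, 1.0)
    for (a, b), value in zip(pairs, p):
        probs[a, b] = probs[b, a] = value
    return BondingProbabilityMatrix(probs)


def pair_training_data(
    proteins, patterns, feature_set: FeatureFunctionSet
) -> Tuple[np.ndarray, np.ndarray]:
    """Stack pair encodings and bonded/non-bonded labels over proteins."""
    rows, labels = [], []
    for protein in proteins:
        truth = patterns.get(protein.id)
        bonds = truth.bonds if truth is not None else frozenset()
        for a in range(protein.n_cys):
            for b in range(a + 1, protein.n_cys):
                rows.append(encode_pair(protein, (a, b), feature_set))
                labels.append(1 if (a, b) in bonds else 0)
    if not rows:
        raise ValueError("no cysteine pairs in the training proteins")
    return np.vstack(rows), np.array(labels, dtype=int)
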