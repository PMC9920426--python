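"""Classifiers and detection metrics.

The deployed detector is a from-scratch k-nearest-neighbour vote with
Euclidean distance — the algorithm simple enough to run on a watch with no
external libraries. "Training" is dataset storage. Deterministic tie rules:

* distance ties at the k-th neighbour resolve by training-point insertion
  order (stable sort);
* vote ties predict Fall — a missed fall costs more than a false alarm.

SVM and decision-tree variants used by the offline configuration grid are
thin adapters over scikit-learn; they are never part of the on-watch path.

Fall is the positive class in all metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import ADL, FALL
from .features import FeatureVector


@dataclass(frozen=True)
class LabeledPoint:
    """One stored training point: features, label, and where it came from."""

    features: np.ndarray
    label: str
    provenance: str = "seed-dataset"  # or "user-feedback"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "features", np.asarray(self.features, dtype=float).ravel()
        )
        if self.label not in (FALL, ADL):
            raise ValueError(f"label must be {FALL!r} or {ADL!r}")
        if self.provenance not in ("seed-dataset", "user-feedback"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


def euclidean_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """sqrt(sum((a_i - b_i)^2)); the straight-line path between points."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def _as_matrix(train: Sequence[LabeledPoint]) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([p.features for p in train])
    y = np.array([p.label for p in train])
    return X, y


def knn_predict(
    train: Sequence[LabeledPoint], x: Sequence[float], k: int = 3
) -> str:
    """Majority label among the k nearest training points."""
    if not train:
        raise ValueError("empty training set")
    if not (1 <= k <= len(train)):
        raise ValueError(f"k must be in [1, {len(train)}], got {k}")
    X, y = _as_matrix(train)
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != X.shape[1]:
        raise ValueError("query dimensionality differs from training set")
    d = np.sqrt(np.sum((X - x) ** 2, axis=1))
    order = np.argsort(d, kind="stable")[:k]
    fall_votes = int(np.sum(y[order] == FALL))
    return FALL if fall_votes * 2 >= k else ADL


def knn_predict_batch(
    train_X: np.ndarray, train_y: np.ndarray, queries: np.ndarray, k: int
) -> np.ndarray:
    """Vectorised kNN over many queries (same tie rules as knn_predict)."""
    if train_X.shape[0] == 0:
        raise ValueError("empty training set")
    if not (1 <= k <= train_X.shape[0]):
        raise ValueError(f"k must be in [1, {train_X.shape[0]}], got {k}")
    # Squared distances suffice for ranking and avoid an n*m sqrt.
    d2 = (
        np.sum(queries**2, axis=1)[:, None]
        + np.sum(train_X**2, axis=1)[None, :]
        - 2.0 * queries @ train_X.T
    )
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    fall_votes = np.sum(train_y[order] == FALL, axis=1)
    return np.where(fall_votes * 2 >= k, FALL, ADL)


class KnnClassifier:
    """Dataset-storing kNN exposing the grid's fit/predict interface."""

    def __init__(self, k: int = 3):
        self.k = k
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: Sequence[str]) -> "KnnClassifier":
        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._X is None or self._y is None:
            raise ValueError("classifier not fitted")
        return knn_predict_batch(self._X, self._y, np.asarray(X, dtype=float), self.k)


class SklearnAdapter:
    """Wraps a scikit-learn estimator behind the same fit/predict surface."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y):
        self.estimator.fit(np.asarray(X, dtype=float), np.asarray(y))
        return self

    def predict(self, X):
        return np.asarray(self.estimator.predict(np.asarray(X, dtype=float)))


#: Algorithm identifiers of the configuration grid: 10 kNN variants, 2 SVM
#: kernels, 3 decision-tree splitting criteria.
GRID_ALGORITHMS: tuple[str, ...] = tuple(
    [f"knn{k}" for k in range(1, 11)]
    + ["svm_rbf", "svm_poly", "dt_gini", "dt_entropy", "dt_log_loss"]
)


def make_classifier(algorithm: str, seed: int = 0):
    """Instantiate a grid algorithm by identifier."""
    if algorithm.startswith("knn"):
        return KnnClassifier(k=int(algorithm[3:]))
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    if algorithm == "svm_rbf":
        return SklearnAdapter(SVC(kernel="rbf"))
    if algorithm == "svm_poly":
        return SklearnAdapter(SVC(kernel="poly"))
    if algorithm.startswith("dt_"):
        criterion = algorithm[3:]
        if criterion not in ("gini", "entropy", "log_loss"):
            raise ValueError(f"unknown tree criterion {criterion!r}")
        return SklearnAdapter(DecisionTreeClassifier(criterion=criterion, random_state=seed))
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(true_labels: Sequence[str], predicted: Sequence[str]) -> ConfusionCounts:
    """Count TP/TN/FP/FN with Fall as the positive class."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted)
    if t.shape != p.shape:
        raise ValueError("label sequences differ in length")
    return ConfusionCounts(
        tp=int(np.sum((t == FALL) & (p == FALL))),
        tn=int(np.sum((t == ADL) & (p == ADL))),
        fp=int(np.sum((t == ADL) & (p == FALL))),
        fn=int(np.sum((t == FALL) & (p == ADL))),
    )


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, sensitivity TP/(TP+FN) and specificity TN/(TN+FP).

    A metric whose denominator is zero is reported as None (undefined),
    never as NaN.
    """
    return {
        "accuracy": (c.tp + c.tn) / c.total if c.total else None,
        "sensitivity": c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None,
        "specificity": c.tn / (c.tn + c.fp) if (c.tn + c.fp) else None,
    }
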