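"""In-repo classifiers behind one fit/predict surface.

Two small classifiers cover the indicator pipelines:

* :class:`GainRatioTree` — an axis-aligned binary decision tree in the C4.5
  family: numeric splits are chosen by maximal information-gain ratio with
  thresholds at midpoints of sorted observed values, leaves take the
  majority label, and growth stops at pure nodes or the minimum leaf size.
* :class:`DistanceWeightedKNN` — a distance-weighted k-nearest-neighbour
  classifier (inverse-distance weights over features standardized by the
  training mean/sd), standing in for entropic instance-based learners.

Both are deterministic given the training rows and seed: ties in split
choice go to the first feature and smallest threshold, and ties in vote
weight go to the smallest label.  The :func:`fit_classifier` /
:func:`predict` pair wraps them behind a single interface keyed by
:class:`ClassifierKind`, so a library classifier can be swapped in without
touching the indicator code.
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .errors import ContractError, ParameterError

__all__ = [
    "ClassifierKind",
    "ClassifierModel",
    "GainRatioTree",
    "DistanceWeightedKNN",
    "fit_classifier",
    "predict",
]


class ClassifierKind(str, enum.Enum):
    DECISION_TREE = "decision_tree"
    INSTANCE_BASED = "instance_based"


def _entropy(labels: Sequence[int]) -> float:
    n = len(labels)
    out = 0.0
    for count in Counter(labels).values():
        p = count / n
        out -= p * math.log2(p)
    return out


def _majority(labels: Sequence[int]) -> int:
    counts = Counter(labels)
    best = max(counts.values())
    return min(label for label, c in counts.items() if c == best)


@dataclass
class _TreeNode:
    feature: int | None = None
    threshold: float | None = None
    label: int | None = None
    left: "_TreeNode | None" = None
    right: "_TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


class GainRatioTree:
    """C4.5-style binary decision tree over numeric features."""

    def __init__(self, min_leaf_size: int = 2):
        if min_leaf_size < 1:
            raise ParameterError("min_leaf_size must be >= 1")
        self.min_leaf_size = min_leaf_size
        self.root: _TreeNode | None = None

    def fit(self, X: Sequence[Sequence[float]], y: Sequence[int]) -> "GainRatioTree":
        if len(X) != len(y) or not X:
            raise ParameterError("X and y must be non-empty and aligned")
        self.n_features_ = len(X[0])
        self.root = self._grow([list(row) for row in X], list(y))
        return self

    def _best_split(
        self, X: list[list[float]], y: list[int]
    ) -> tuple[int, float] | None:
        n = len(y)
        base = _entropy(y)
        best: tuple[float, int, float] | None = None  # (gain_ratio, feat, thr)
        for j in range(self.n_features_):
            order = sorted(range(n), key=lambda i: X[i][j])
            values = [X[i][j] for i in order]
            labels = [y[i] for i in order]
            for i in range(n - 1):
                if values[i] == values[i + 1]:
                    continue
                n_left = i + 1
                n_right = n - n_left
                if n_left < self.min_leaf_size or n_right < self.min_leaf_size:
                    continue
                threshold = (values[i] + values[i + 1]) / 2.0
                gain = base - (
                    n_left / n * _entropy(labels[:n_left])
                    + n_right / n * _entropy(labels[n_left:])
                )
                if gain <= 1e-12:
                    continue
                w_left, w_right = n_left / n, n_right / n
                split_info = -(w_left * math.log2(w_left) + w_right * math.log2(w_right))
                ratio = gain / split_info
                if best is None or ratio > best[0] + 1e-12:
                    best = (ratio, j, threshold)
        if best is None:
            return None
        return best[1], best[2]

    def _grow(self, X: list[list[float]], y: list[int]) -> _TreeNode:
        if len(set(y)) == 1 or len(y) < 2 * self.min_leaf_size:
            return _TreeNode(label=_majority(y))
        split = self._best_split(X, y)
        if split is None:
            return _TreeNode(label=_majority(y))
        j, threshold = split
        left_idx = [i for i in range(len(y)) if X[i][j] <= threshold]
        right_idx = [i for i in range(len(y)) if X[i][j] > threshold]
        return _TreeNode(
            feature=j,
            threshold=threshold,
            left=self._grow([X[i] for i in left_idx], [y[i] for i in left_idx]),
            right=self._grow([X[i] for i in right_idx], [y[i] for i in right_idx]),
        )

    def predict_one(self, x: Sequence[float]) -> int:
        if self.root is None:
            raise ContractError("predict before fit")
        if len(x) != self.n_features_:
            raise ContractError(
                f"expected {self.n_features_} features, got {len(x)}"
            )
        node = self.root
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.label

    def predict(self, X: Sequence[Sequence[float]]) -> list[int]:
        return [self.predict_one(x) for x in X]


class DistanceWeightedKNN:
    """k-NN with inverse-distance weights over standardized features."""

    def __init__(self, k: int = 3):
        if k < 1:
            raise ParameterError("k must be >= 1")
        self.k = k

    def fit(self, X: Sequence[Sequence[float]], y: Sequence[int]) -> "DistanceWeightedKNN":
        if len(X) != len(y) or not X:
            raise ParameterError("X and y must be non-empty and aligned")
        self.n_features_ = len(X[0])
        n = len(X)
        self.mean_ = [sum(row[j] for row in X) / n for j in range(self.n_features_)]
        self.sd_ = []
        for j in range(self.n_features_):
            var = sum((row[j] - self.mean_[j]) ** 2 for row in X) / n
            sd = math.sqrt(var)
            self.sd_.append(sd if sd > 0 else 1.0)  # constant feature: no scaling
        self.X_ = [self._standardize(row) for row in X]
        self.y_ = list(y)
        return self

    def _standardize(self, x: Sequence[float]) -> list[float]:
        return [(x[j] - self.mean_[j]) / self.sd_[j] for j in range(self.n_features_)]

    def predict_one(self, x: Sequence[float]) -> int:
        if not hasattr(self, "X_"):
            raise ContractError("predict before fit")
        if len(x) != self.n_features_:
            raise ContractError(
                f"expected {self.n_features_} features, got {len(x)}"
            )
        z = self._standardize(x)
        dists = [
            (math.dist(z, row), label) for row, label in zip(self.X_, self.y_)
        ]
        dists.sort(key=lambda t: (t[0], t[1]))
        neighbours = dists[: min(self.k, len(dists))]
        # an exact match decides outright (infinite weight)
        exact = [label for d, label in neighbours if d == 0.0]
        if exact:
            return _majority(exact)
        votes: dict[int, float] = {}
        for d, label in neighbours:
            votes[label] = votes.get(label, 0.0) + 1.0 / d
        best = max(votes.values())
        return min(l for l, w in votes.items() if w >= best - 1e-12)

    def predict(self, X: Sequence[Sequence[float]]) -> list[int]:
        return [self.predict_one(x) for x in X]


@dataclass
class ClassifierModel:
    """A fitted classifier plus its training metadata."""

    kind: ClassifierKind
    estimator: object
    feature_names: tuple[str, ...]
    n_rows: int
    seed: int
    labels: tuple[int, ...] = field(default_factory=tuple)


def fit_classifier(
    rows: Sequence,
    kind: ClassifierKind,
    seed: int = 0,
    *,
    k: int = 3,
    min_leaf_size: int = 2,
) -> ClassifierModel:
    """Fit a classifier on labeled feature vectors.

    ``rows`` are :class:`~wearharmonize.indicators.FeatureVector` objects (or
    anything with ``features`` mapping and integer ``label``).  The feature
    order is the sorted union of names; missing entries carry sentinel -1.
    Deterministic given rows and seed.
    """
    labeled = [r for r in rows if r.label is not None]
    if not labeled:
        raise ParameterError("no labeled rows to fit on")
    names = tuple(sorted({name for r in labeled for name in r.features}))
    X = [[float(r.features.get(n, -1)) for n in names] for r in labeled]
    y = [int(r.label) for r in labeled]
    if kind is ClassifierKind.DECISION_TREE:
        estimator = GainRatioTree(min_leaf_size=min_leaf_size).fit(X, y)
    elif kind is ClassifierKind.INSTANCE_BASED:
        estimator = DistanceWeightedKNN(k=k).fit(X, y)
    else:  # pragma: no cover
        raise ParameterError(f"unknown classifier kind {kind!r}")
    return ClassifierModel(
        kind=kind,
        estimator=estimator,
        feature_names=names,
        n_rows=len(labeled),
        seed=seed,
        labels=tuple(sorted(set(y))),
    )


def predict(model: ClassifierModel, x) -> int:
    """Predict the label of one feature vector with a fitted model."""
    missing = [n for n in model.feature_names if n not in x.features]
    unknown = [n for n in x.features if n not in model.feature_names]
    if missing or unknown:
        raise ContractError(
            f"feature set mismatch: missing {missing}, unknown {unknown}"
        )
    row = [float(x.features[n]) for n in model.feature_names]
    return model.estimator.predict_one(row)
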