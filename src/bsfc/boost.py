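"""Gentle AdaBoost with split-limited regression-tree weak learners.

Gentle boosting fits an additive model F(x) = sum_m nu * f_m(x) to
labels y in {-1, +1}: each cycle fits a regression tree f_m to y by
*weighted least squares* under the current example weights, adds it
with shrinkage nu, and reweights

    w_i <- w_i * exp(-y_i * nu * f_m(x_i)),   then renormalize.

Because f_m is a least-squares fit of y (a weighted class-probability
difference bounded in [-1, 1] at each leaf) rather than a log-odds
step, the updates are bounded — "gentle" — which makes the variant
robust on noisy, overlapping classes. The predicted class is sign(F).

The weak-learner fit itself delegates to
:class:`sklearn.tree.DecisionTreeRegressor` (a weighted-least-squares
tree fitter); the boosting loop, shrinkage and reweighting live here.
Trained models serialize to self-describing JSON (flattened tree
arrays, shrinkage) so they are portable across languages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from .config import BoostHyperparams

__all__ = ["TreeArrays", "GentleBoostModel", "fit_gentleboost"]


@dataclass
class TreeArrays:
    """Flattened binary regression tree.

    Node i sends a sample left when x[feature[i]] <= threshold[i];
    leaves have feature -1 and carry their value in ``value``.
    """

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray

    @classmethod
    def from_sklearn(cls, tree: DecisionTreeRegressor) -> "TreeArrays":
        t = tree.tree_
        return cls(
            children_left=t.children_left.copy(),
            children_right=t.children_right.copy(),
            feature=t.feature.copy(),
            threshold=t.threshold.copy(),
            value=t.value.reshape(-1).copy(),
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = self.feature[node] >= 0
        while active.any():
            idx = np.flatnonzero(active)
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(
                go_left, self.children_left[nd], self.children_right[nd]
            )
            active = self.feature[node] >= 0
        return self.value[node]

    def to_dict(self) -> dict:
        return {
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "value": self.value.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeArrays":
        return cls(
            children_left=np.asarray(d["children_left"], dtype=np.int64),
            children_right=np.asarray(d["children_right"], dtype=np.int64),
            feature=np.asarray(d["feature"], dtype=np.int64),
            threshold=np.asarray(d["threshold"], dtype=float),
            value=np.asarray(d["value"], dtype=float),
        )

    @property
    def n_internal_splits(self) -> int:
        return int(np.sum(self.feature >= 0))


@dataclass
class GentleBoostModel:
    """An additive ensemble of shrunken regression trees."""

    trees: list[TreeArrays] = field(default_factory=list)
    learning_rate: float = 0.899

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        F = np.zeros(X.shape[0])
        for tree in self.trees:
            F += self.learning_rate * tree.predict(X)
        return F

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class labels in {-1, +1}; the zero decision boundary maps to -1."""
        return np.where(self.decision_function(X) > 0, 1, -1)

    def to_dict(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "trees": [t.to_dict() for t in self.trees],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GentleBoostModel":
        return cls(
            trees=[TreeArrays.from_dict(t) for t in d["trees"]],
            learning_rate=float(d["learning_rate"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "GentleBoostModel":
        return cls.from_dict(json.loads(s))


def fit_gentleboost(
    X: np.ndarray,
    y: np.ndarray,
    hp: BoostHyperparams | None = None,
    seed: int = 0,
) -> GentleBoostModel:
    """Train one Gentle-AdaBoost model.

    ``y`` must contain both classes, coded {-1, +1}. Deterministic for
    a fixed seed (the seed breaks ties in the tree fitter's feature
    ordering).
    """
    hp = hp or BoostHyperparams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite values in training data")
    classes = np.unique(y)
    if not np.array_equal(classes, [-1, 1]):
        if classes.size < 2:
            raise ValueError("training labels contain a single class")
        raise ValueError(f"labels must be coded -1/+1, got {classes}")

    n = X.shape[0]
    w = np.full(n, 1.0 / n)
    F = np.zeros(n)
    model = GentleBoostModel(learning_rate=hp.learning_rate)
    rng = np.random.default_rng(seed)
    for _ in range(hp.n_learning_cycles):
        learner = DecisionTreeRegressor(
            max_leaf_nodes=hp.max_splits + 1,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        learner.fit(X, y, sample_weight=w)
        tree = TreeArrays.from_sklearn(learner)
        fm = tree.predict(X)
        model.trees.append(tree)
        F += hp.learning_rate * fm
        w = w * np.exp(-y * hp.learning_rate * fm)
        total = w.sum()
        if total <= 0 or not np.isfinite(total):
            break  # weights degenerate: every example fit exactly
        w /= total
    return model
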