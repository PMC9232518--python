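"""Balanced ensemble training and sequential cascade evaluation.

The labeled event stream is grossly imbalanced (tens of non-cluster
events per true cluster). Rather than reweighting, an ensemble of
``n_models`` (default 50) Gentle-boosted tree models is trained: every
model sees the *same* positive (CTCC) rows plus a fresh equal-size
random sample of negative (NC) rows, so each model learns a different
slice of the negative population while never diluting the positives.

Evaluation is a sequential cascade: the test set enters model 1; only
events predicted positive survive to model 2; and so on through all
models. An event rejected at any stage is a non-cluster thereafter.
Survivor sets are nested, so with each stage specificity can only rise
and sensitivity only fall — performance converges to a maximal limit as
stages accumulate.

The day-combination harness retrains the whole ensemble on every
C(n_days, k) choose-k subset of training days (286 for 10 of 13) and
aggregates the four metrics across plans.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .boost import GentleBoostModel, fit_gentleboost
from .config import BoostHyperparams
from .metrics import all_metrics, confusion

__all__ = [
    "Cascade",
    "balanced_resample",
    "train_cascade",
    "evaluate_cascade",
    "enumerate_training_splits",
    "metrics_by_stage",
    "run_evaluation_suite",
]


@dataclass
class Cascade:
    """Ordered ensemble evaluated as a sequential positive filter."""

    models: list[GentleBoostModel] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.models)

    def to_json(self) -> str:
        return json.dumps({"models": [m.to_dict() for m in self.models]})

    @classmethod
    def from_json(cls, s: str) -> "Cascade":
        d = json.loads(s)
        return cls(models=[GentleBoostModel.from_dict(m) for m in d["models"]])

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path: str) -> "Cascade":
        with open(path) as fh:
            return cls.from_json(fh.read())


def balanced_resample(
    n_positive: int, nc_pool: np.ndarray, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw ``n_positive`` distinct NC row indices, uniform without
    replacement, from the pool."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    nc_pool = np.asarray(nc_pool)
    if nc_pool.size < n_positive:
        raise ValueError(
            f"NC pool ({nc_pool.size}) smaller than positive count ({n_positive})"
        )
    return rng.choice(nc_pool, size=n_positive, replace=False)


def train_cascade(
    X: np.ndarray,
    y: np.ndarray,
    hp: BoostHyperparams | None = None,
    n_models: int = 50,
    seed: int = 0,
) -> Cascade:
    """Train the balanced ensemble.

    Every model is fit on all positive rows (y == +1) plus an
    independent balanced resample of the negative rows; per-model seeds
    derive from the master seed.
    """
    hp = hp or BoostHyperparams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == -1)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("training data must contain both classes")
    ss = np.random.SeedSequence(seed)
    cascade = Cascade()
    for child in ss.spawn(n_models):
        rng = np.random.default_rng(child)
        nc_sample = balanced_resample(pos.size, neg, rng)
        rows = np.concatenate([pos, nc_sample])
        model = fit_gentleboost(
            X[rows], y[rows], hp, seed=int(rng.integers(0, 2**31 - 1))
        )
        cascade.models.append(model)
    return cascade


def evaluate_cascade(
    cascade: Cascade, X: np.ndarray
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Run the sequential cascade on a test matrix.

    Returns ``(predictions, survivors)`` where ``predictions`` is a
    {-1, +1} vector (+1 = survived every stage) and ``survivors[k]``
    holds the row indices still positive after stage k (survivors[0] is
    all rows, before any model).
    """
    X = np.asarray(X, dtype=float)
    alive = np.arange(X.shape[0])
    survivors = [alive.copy()]
    for model in cascade.models:
        if alive.size == 0:
            survivors.append(alive.copy())
            continue
        pred = model.predict(X[alive])
        alive = alive[pred == 1]
        survivors.append(alive.copy())
    predictions = np.full(X.shape[0], -1, dtype=int)
    predictions[alive] = 1
    return predictions, survivors


def enumerate_training_splits(
    days: list[str], k: int = 10
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All C(n, k) (training-days, validation-days) pairs in
    deterministic lexicographic order."""
    days = list(days)
    if k > len(days):
        raise ValueError(f"cannot choose {k} of {len(days)} days")
    plans = []
    for combo in itertools.combinations(range(len(days)), k):
        train = tuple(days[i] for i in combo)
        val = tuple(d for i, d in enumerate(days) if i not in combo)
        plans.append((train, val))
    return plans


def metrics_by_stage(
    cascade: Cascade, X: np.ndarray, y: np.ndarray
) -> list[dict[str, float]]:
    """The four metrics after each cascade stage (the convergence
    curve): entry k is performance using only the first k models."""
    _, survivors = evaluate_cascade(cascade, X)
    out = []
    for alive in survivors[1:]:
        pred = np.full(y.shape[0], -1, dtype=int)
        pred[alive] = 1
        out.append(all_metrics(confusion(y, pred)))
    return out


def run_evaluation_suite(
    X_train: np.ndarray,
    y_train: np.ndarray,
    train_days: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    plans: list[tuple[tuple[str, ...], tuple[str, ...]]],
    hp: BoostHyperparams | None = None,
    n_models: int = 50,
    seed: int = 0,
    test_days: np.ndarray | None = None,
) -> dict:
    """Retrain and evaluate the cascade under every day-split plan.

    For each plan the ensemble is trained on the plan's training days
    only and evaluated on the fixed held-out test set; the summary
    reports the mean and sample std of each metric across plans. Test
    days must be disjoint from every training day.
    """
    train_days = np.asarray(train_days, dtype=object)
    if test_days is not None:
        overlap = set(np.unique(test_days)) & set(np.unique(train_days))
        if overlap:
            raise ValueError(f"test days overlap training days: {sorted(overlap)}")
    ss = np.random.SeedSequence(seed)
    per_plan = []
    for (plan_train, _), child in zip(plans, ss.spawn(len(plans))):
        mask = np.isin(train_days, plan_train)
        cascade = train_cascade(
            X_train[mask], y_train[mask], hp, n_models,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        pred, _ = evaluate_cascade(cascade, X_test)
        m = all_metrics(confusion(y_test, pred))
        m["train_days"] = list(plan_train)
        per_plan.append(m)
    summary = {}
    for key in ("purity", "sensitivity", "specificity", "accuracy"):
        vals = np.array([p[key] for p in per_plan], dtype=float)
        ok = np.isfinite(vals)
        summary[key] = {
            "mean": float(np.mean(vals[ok])) if ok.any() else float("nan"),
            "std": float(np.std(vals[ok], ddof=1)) if ok.sum() > 1 else 0.0,
            "n_defined": int(ok.sum()),
        }
    return {"per_plan": per_plan, "summary": summary, "n_plans": len(plans)}
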