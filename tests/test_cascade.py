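import math

import numpy as np
import pytest

from bsfc.boost import GentleBoostModel, TreeArrays
from bsfc.cascade import (
    Cascade,
    balanced_resample,
    enumerate_training_splits,
    evaluate_cascade,
    metrics_by_stage,
    run_evaluation_suite,
    train_cascade,
)
from bsfc.config import BoostHyperparams

HP_FAST = BoostHyperparams(n_learning_cycles=8, max_splits=8)


def feature_blobs(n_pos=40, n_neg=400, dim=8, sep=5.0, seed=0,
                  days=("d0", "d1")):
    rng = np.random.default_rng(seed)
    mu = np.zeros(dim)
    mu[0] = sep
    X = np.vstack([
        rng.normal(mu, 1.0, (n_pos, dim)),
        rng.normal(0.0, 1.0, (n_neg, dim)),
    ])
    y = np.array([1] * n_pos + [-1] * n_neg)
    day = np.array([days[i % len(days)] for i in range(n_pos + n_neg)],
                   dtype=object)
    return X, y, day


def constant_model(value: float) -> GentleBoostModel:
    """A one-leaf 'tree' that predicts ``value`` everywhere."""
    tree = TreeArrays(
        children_left=np.array([-1]), children_right=np.array([-1]),
        feature=np.array([-1]), threshold=np.array([-2.0]),
        value=np.array([value]),
    )
    return GentleBoostModel(trees=[tree], learning_rate=1.0)


class TestBalancedResample:
    def test_pool_equal_to_positives_returns_whole_pool(self):
        pool = np.arange(10)
        out = balanced_resample(10, pool, 0)
        assert sorted(out) == list(range(10))

    def test_sample_is_distinct_and_right_sized(self):
        out = balanced_resample(2285, np.arange(44_964), 1)
        assert out.size == 2285 and np.unique(out).size == 2285

    def test_seed_controls_sample(self):
        pool = np.arange(1000)
        a = balanced_resample(100, pool, 7)
        b = balanced_resample(100, pool, 7)
        c = balanced_resample(100, pool, 8)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError):
            balanced_resample(11, np.arange(10), 0)


class TestTrainCascade:
    def test_single_model_reduces_to_balanced_fit(self):
        X, y, _ = feature_blobs()
        cascade = train_cascade(X, y, HP_FAST, n_models=1, seed=0)
        assert len(cascade) == 1

    def test_every_model_separates_separable_data(self):
        X, y, _ = feature_blobs(sep=8.0)
        cascade = train_cascade(X, y, HP_FAST, n_models=5, seed=0)
        pos = X[y == 1]
        for model in cascade.models:
            assert np.all(model.predict(pos) == 1)

    def test_master_seed_reproduces_predictions(self):
        X, y, _ = feature_blobs(sep=2.0)
        probe = np.random.default_rng(5).normal(size=(200, X.shape[1]))
        pred_a, _ = evaluate_cascade(train_cascade(X, y, HP_FAST, 5, seed=3),
                                     probe)
        pred_b, _ = evaluate_cascade(train_cascade(X, y, HP_FAST, 5, seed=3),
                                     probe)
        np.testing.assert_array_equal(pred_a, pred_b)

    def test_missing_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 4))
        with pytest.raises(ValueError):
            train_cascade(X, np.ones(30, dtype=int), HP_FAST, 2, seed=0)

    def test_serialization_round_trip(self, tmp_path):
        X, y, _ = feature_blobs(sep=3.0)
        cascade = train_cascade(X, y, HP_FAST, 3, seed=0)
        path = tmp_path / "cascade.json"
        cascade.save(path)
        clone = Cascade.load(path)
        probe = np.random.default_rng(1).normal(size=(100, X.shape[1]))
        np.testing.assert_array_equal(evaluate_cascade(cascade, probe)[0],
                                      evaluate_cascade(clone, probe)[0])


class TestEvaluateCascade:
    def test_empty_cascade_predicts_all_positive(self):
        X = np.zeros((7, 3))
        pred, survivors = evaluate_cascade(Cascade(), X)
        assert np.all(pred == 1)
        assert survivors[0].size == 7

    def test_always_negative_model_kills_everything(self):
        X = np.zeros((7, 3))
        pred, survivors = evaluate_cascade(
            Cascade(models=[constant_model(-1.0)]), X
        )
        assert np.all(pred == -1) and survivors[-1].size == 0

    def test_survivor_sets_are_nested_and_non_increasing(self):
        X, y, _ = feature_blobs(sep=1.0, seed=2)  # heavy class overlap
        cascade = train_cascade(X, y, HP_FAST, 10, seed=4)
        probe = np.random.default_rng(3).normal(size=(300, X.shape[1]))
        _, survivors = evaluate_cascade(cascade, probe)
        for prev, cur in zip(survivors, survivors[1:]):
            assert cur.size <= prev.size
            assert set(cur).issubset(set(prev))

    def test_stage_metrics_monotone(self):
        X, y, _ = feature_blobs(sep=2.0, seed=6)
        Xte, yte, _ = feature_blobs(sep=2.0, seed=7)
        cascade = train_cascade(X, y, HP_FAST, 10, seed=5)
        curve = metrics_by_stage(cascade, Xte, yte)
        spec = [m["specificity"] for m in curve]
        sens = [m["sensitivity"] for m in curve]
        assert all(b >= a - 1e-9 for a, b in zip(spec, spec[1:]))
        assert all(b <= a + 1e-9 for a, b in zip(sens, sens[1:]))


class TestSplitEnumeration:
    def test_thirteen_choose_ten_gives_286(self):
        days = [f"d{i}" for i in range(13)]
        plans = enumerate_training_splits(days, 10)
        assert len(plans) == math.comb(13, 10) == 286
        train, val = plans[0]
        assert len(train) == 10 and len(val) == 3
        assert set(train) | set(val) == set(days)

    def test_choose_all_gives_one_plan(self):
        assert len(enumerate_training_splits(list("abc"), 3)) == 1

    def test_five_choose_three_gives_ten(self):
        assert len(enumerate_training_splits(list("abcde"), 3)) == 10

    def test_plans_are_unique_and_lexicographic(self):
        plans = enumerate_training_splits(list("abcde"), 3)
        trains = [p[0] for p in plans]
        assert len(set(trains)) == len(trains)
        assert trains == sorted(trains)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            enumerate_training_splits(["a"], 2)


class TestEvaluationSuite:
    def test_separable_single_plan_is_perfect(self):
        Xtr, ytr, days = feature_blobs(sep=8.0, seed=0)
        Xte, yte, _ = feature_blobs(sep=8.0, seed=1)
        plans = [(("d0", "d1"), ())]
        res = run_evaluation_suite(Xtr, ytr, days, Xte, yte, plans,
                                   HP_FAST, n_models=3, seed=0)
        for key in ("purity", "sensitivity", "specificity", "accuracy"):
            assert res["summary"][key]["mean"] == pytest.approx(100.0)

    def test_aggregate_mean_within_plan_range(self):
        Xtr, ytr, days = feature_blobs(sep=1.5, seed=2,
                                       days=("d0", "d1", "d2"))
        Xte, yte, _ = feature_blobs(sep=1.5, seed=3)
        plans = enumerate_training_splits(["d0", "d1", "d2"], 2)
        res = run_evaluation_suite(Xtr, ytr, days, Xte, yte, plans,
                                   HP_FAST, n_models=2, seed=1)
        for key in ("sensitivity", "specificity"):
            vals = [p[key] for p in res["per_plan"]]
            s = res["summary"][key]
            assert min(vals) - 1e-9 <= s["mean"] <= max(vals) + 1e-9
            assert s["std"] >= 0.0

    def test_train_test_day_overlap_rejected(self):
        Xtr, ytr, days = feature_blobs(seed=0)
        with pytest.raises(ValueError):
            run_evaluation_suite(
                Xtr, ytr, days, Xtr, ytr, [(("d0",), ())],
                HP_FAST, n_models=1, seed=0,
                test_days=np.array(["d0"] * len(ytr), dtype=object),
            )
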