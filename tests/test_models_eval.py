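"""Split discipline, SMOTE contract, training and evaluation metrics."""

import numpy as np
import pandas as pd
import pytest

from matchload.models_eval import (
    ModelSpec,
    SplitSpec,
    evaluate,
    run_experiment,
    smote_resample,
    split_train_test,
    train_model,
)

LIGHT_TREE = ModelSpec("decision_tree", n_search_iterations=5, cv_folds=3, seed=0)


def toy_rows(n_matches=20, periods=18, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for m in range(n_matches):
        signal = rng.normal(0, 1)
        for p in range(1, periods + 1):
            rows.append(
                {"match_id": f"M{m}", "player_id": "P1", "period": p,
                 "pct_avg_distance": 100 + 10 * signal + rng.normal(0, 1),
                 "pct_avg_summed_distance": 100 + 10 * signal + rng.normal(0, 0.5),
                 "label": int(signal < 0)}
            )
    return pd.DataFrame(rows)


class TestSplit:
    def test_grouped_split_proportions(self):
        rows = toy_rows(10)
        train, test = split_train_test(rows, SplitSpec(seed=1))
        n_train = train[["match_id", "player_id"]].drop_duplicates().shape[0]
        n_test = test[["match_id", "player_id"]].drop_duplicates().shape[0]
        assert (n_train, n_test) == (7, 3)
        assert len(train) + len(test) == len(rows)

    def test_same_seed_same_split(self):
        rows = toy_rows(15)
        a = split_train_test(rows, SplitSpec(seed=9))
        b = split_train_test(rows, SplitSpec(seed=9))
        assert a[0].index.equals(b[0].index) and a[1].index.equals(b[1].index)

    def test_no_player_match_spans_both_sides_over_many_seeds(self):
        rows = toy_rows(13)
        for seed in range(100):
            train, test = split_train_test(rows, SplitSpec(seed=seed))
            tr = set(map(tuple, train[["match_id", "player_id"]].to_numpy()))
            te = set(map(tuple, test[["match_id", "player_id"]].to_numpy()))
            assert tr.isdisjoint(te)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError, match="10 player-matches"):
            split_train_test(toy_rows(5), SplitSpec())

    def test_row_split_mode_keeps_proportions(self):
        rows = toy_rows(10)
        train, test = split_train_test(rows, SplitSpec(unit="rows", seed=0))
        assert len(train) == int(round(0.7 * len(rows)))


class TestSmote:
    def test_counts_balanced_100_40(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (100, 3)), rng.normal(3, 1, (40, 3))])
        y = np.array([0] * 100 + [1] * 40)
        Xr, yr = smote_resample(X, y, seed=1)
        assert (yr == 0).sum() == 100 and (yr == 1).sum() == 100
        # original rows preserved verbatim at the front
        assert np.array_equal(Xr[: len(X)], X)

    def test_already_balanced_unchanged(self):
        X = np.arange(40, dtype=float).reshape(20, 2)
        y = np.array([0, 1] * 10)
        Xr, yr = smote_resample(X, y, seed=1)
        assert np.array_equal(Xr, X) and np.array_equal(yr, y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            smote_resample(np.zeros((10, 2)), np.zeros(10), seed=0)

    def test_tiny_minority_reduces_k_with_warning(self):
        X = np.vstack([np.zeros((20, 2)), [[1, 1], [2, 2], [3, 3]]])
        y = np.array([0] * 20 + [1] * 3)
        with pytest.warns(UserWarning, match="reducing k"):
            Xr, yr = smote_resample(X, y, k_neighbors=5, seed=0)
        assert (yr == 1).sum() == 20

    def test_synthetic_rows_interpolate_minority_neighbours(self):
        """Every synthetic sample lies coordinate-wise between minority points."""
        rng = np.random.default_rng(3)
        Xmin = rng.uniform(10, 11, (15, 4))
        X = np.vstack([rng.uniform(0, 1, (60, 4)), Xmin])
        y = np.array([0] * 60 + [1] * 15)
        Xr, yr = smote_resample(X, y, seed=3)
        new = Xr[len(X):]
        assert np.all(new >= Xmin.min(axis=0) - 1e-12)
        assert np.all(new <= Xmin.max(axis=0) + 1e-12)


class TestTraining:
    def test_separable_data_perfect_training_f1(self):
        X = np.vstack([np.full((30, 2), 0.0), np.full((30, 2), 5.0)])
        y = np.array([0] * 30 + [1] * 30)
        model = train_model(X, y, LIGHT_TREE)
        assert (model.predict(X) == y).all()

    def test_fixed_seed_selects_same_hyperparameters(self):
        rows = toy_rows(30, seed=2)
        X = rows[["period", "pct_avg_distance", "pct_avg_summed_distance"]].to_numpy()
        y = rows["label"].to_numpy()
        m1 = train_model(X, y, LIGHT_TREE)
        m2 = train_model(X, y, LIGHT_TREE)
        assert m1.best_params_ == m2.best_params_
        assert m1.search_trace_ == m2.search_trace_

    def test_permuted_labels_give_chance_level_cv_f1(self):
        """With labels shuffled, balanced-data CV F1 centers on 0.5."""
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (300, 4))
        y = np.array([0, 1] * 150)
        scores = []
        for rep in range(20):
            y_perm = rng.permutation(y)
            model = train_model(
                X, y_perm, ModelSpec("naive_bayes", cv_folds=3, seed=rep)
            )
            scores.append(model.search_trace_[0]["mean_f1"])
        mean = np.mean(scores)
        se = np.std(scores, ddof=1) / np.sqrt(len(scores))
        assert abs(mean - 0.5) < 2.2 * se + 0.02


class TestEvaluate:
    def test_perfect_predictions(self):
        X = np.vstack([np.zeros((20, 2)), np.ones((20, 2)) * 5])
        y = np.array([0] * 20 + [1] * 20)
        model = train_model(X, y, LIGHT_TREE)
        rep = evaluate(model, X, y, np.tile(np.arange(1, 5), 10))
        assert rep.accuracy == 1.0 and rep.auc == 1.0
        assert rep.precision["underperforming"] == 1.0
        assert rep.recall["underperforming"] == 1.0
        assert rep.f1["performing"] == 1.0

    def test_hand_built_confusion_counts(self):
        """20 test rows scored against hand-computed precision/recall."""

        class Stub:
            classes_ = np.array([0, 1])

            def predict(self, X):
                return np.asarray(X[:, 0] > 0.5, dtype=int)

            def predict_proba(self, X):
                p = np.asarray(X[:, 0], dtype=float)
                return np.column_stack([1 - p, p])

        # truth: 12 performing, 8 underperforming; stub predicts 10 positives,
        # of which 6 are true positives
        X = np.zeros((20, 1))
        X[:10, 0] = 1.0
        y = np.array([1] * 6 + [0] * 4 + [1] * 2 + [0] * 8)
        rep = evaluate(Stub(), X, y, np.ones(20, dtype=int))
        tn, fp, fn, tp = np.array(rep.confusion).ravel()
        assert (tp, fp, fn, tn) == (6, 4, 2, 8)
        assert rep.precision["underperforming"] == pytest.approx(6 / 10)
        assert rep.recall["underperforming"] == pytest.approx(6 / 8)
        assert rep.accuracy == pytest.approx(14 / 20)
        # metrics recomputed from stored confusion counts match exactly
        assert rep.precision["performing"] == pytest.approx(tn / (tn + fn))

    def test_majority_predictor_on_imbalanced_test(self):
        class Majority:
            classes_ = np.array([0, 1])

            def predict(self, X):
                return np.zeros(len(X), dtype=int)

            def predict_proba(self, X):
                return np.column_stack([np.ones(len(X)), np.zeros(len(X))])

        y = np.array([0] * 18 + [1] * 2)
        rep = evaluate(Majority(), np.zeros((20, 2)), y, np.ones(20, dtype=int))
        assert rep.accuracy == pytest.approx(0.9)
        assert rep.recall["underperforming"] == 0.0

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError, match="empty test"):
            evaluate(None, np.zeros((0, 2)), np.array([]), np.array([]))


def test_null_signal_auc_near_half():
    """With the feature-label link broken (labels drawn independently of the
    match), the full pipeline -- split, SMOTE, tuned model -- reports
    chance-level AUC at the 90% threshold instead of leaking optimism."""
    rng = np.random.default_rng(10)
    n_matches = 400
    feats = toy_rows(n_matches, seed=10).drop(columns="label")
    labels = pd.DataFrame(
        {
            "match_id": [f"M{m}" for m in range(n_matches)],
            "player_id": "P1",
            "underperf_90": rng.random(n_matches) < 0.15,
        }
    )
    reports = run_experiment(
        {"distance": feats},
        {"distance": labels},
        thresholds=(0.90,),
        algorithms=("naive_bayes",),
        split=SplitSpec(seed=10),
        seed=10,
    )
    assert abs(reports[0].auc - 0.5) < 0.05
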