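"""Classifier training, prediction, nested CV, and evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from rpiboost import (
    ConfusionCounts,
    ModelConfig,
    compute_metrics,
    nested_cv,
    predict,
    train,
)
from rpiboost.learner import (
    SMALL_PENALTY_GRID,
    counts_from_predictions,
    load_model,
    save_model,
)

FAST = ModelConfig(n_trees=30, max_depth=3, seed=0)


def separable_toy(n=40):
    """Positives on e1, negatives on e2 (plus tiny jitter)."""
    rng = np.random.default_rng(0)
    X = np.zeros((n, 8))
    y = np.arange(n) % 2
    X[y == 1, 0] = 1.0
    X[y == 0, 1] = 1.0
    X += rng.normal(0, 1e-3, X.shape)
    return X, y


class TestConfig:
    def test_published_defaults(self):
        cfg = ModelConfig()
        assert (cfg.n_trees, cfg.learning_rate, cfg.max_depth) == (200, 0.25, 8)
        assert (cfg.l1_penalty, cfg.l2_penalty, cfg.subsample_ratio) == (
            1.12,
            18.51,
            0.9,
        )
        assert cfg.loss == "binary:logistic"
        assert cfg.decision_threshold == 0.5

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(decision_threshold=1.5)

    def test_nonpositive_field_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(n_trees=0)


class TestTrainPredict:
    def test_separable_data_learned_perfectly(self):
        X, y = separable_toy()
        model = train(X, y, ModelConfig())  # published configuration
        probs = np.array([p for p, _ in predict(model, X)])
        assert np.mean((probs >= 0.5) == y) == 1.0
        assert probs[y == 1].min() > 0.9

    def test_single_class_rejected(self):
        X, _ = separable_toy()
        with pytest.raises(ValueError, match="single class"):
            train(X, np.ones(len(X)), FAST)

    def test_nan_features_rejected(self):
        X, y = separable_toy()
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            train(X, y, FAST)

    def test_too_few_rows_rejected(self):
        X, y = separable_toy()
        with pytest.raises(ValueError, match="at least 10"):
            train(X[:6], y[:6], FAST)

    def test_save_load_roundtrip(self, tmp_path):
        X, y = separable_toy()
        model = train(X, y, FAST)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        held = np.random.default_rng(1).random((10, 8))
        np.testing.assert_allclose(
            [p for p, _ in predict(model, held)],
            [p for p, _ in predict(back, held)],
        )

    def test_dimension_mismatch_names_expected(self):
        X, y = separable_toy()
        model = train(X, y, FAST)
        with pytest.raises(ValueError, match="8"):
            predict(model, np.zeros((2, 5)))

    def test_probability_equal_to_threshold_is_positive_call(self):
        X, y = separable_toy()
        model = train(X, y, FAST)
        p0, _ = predict(model, X[:1])[0]
        (_, call), = predict(model, X[:1], threshold=p0)
        assert call is True

    def test_batch_shape_and_order(self):
        X, y = separable_toy()
        model = train(X, y, FAST)
        out = predict(model, X[:7])
        assert len(out) == 7
        singles = [predict(model, X[i : i + 1])[0][0] for i in range(7)]
        np.testing.assert_allclose([p for p, _ in out], singles, rtol=1e-6)


class TestMetrics:
    def test_hand_counts(self):
        m = compute_metrics(ConfusionCounts(TP=3, TN=3, FP=1, FN=1))
        assert m["accuracy"] == m["precision"] == m["recall"] == 0.75
        assert m["f_score"] == pytest.approx(0.75)

    def test_perfect_predictions(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        counts = counts_from_predictions(labels, scores >= 0.5)
        m = compute_metrics(counts, scores, labels)
        assert all(m[k] == 1.0 for k in ("accuracy", "precision", "recall", "f_score", "auroc"))

    def test_f_score_formula(self):
        # precision 0.5, recall 1.0 -> F = 2*0.5/1.5
        m = compute_metrics(ConfusionCounts(TP=2, TN=0, FP=2, FN=0))
        assert m["precision"] == 0.5 and m["recall"] == 1.0
        assert m["f_score"] == pytest.approx(2 * 0.5 / 1.5)

    def test_undefined_precision_warns_and_reports_zero(self):
        with pytest.warns(UserWarning, match="precision"):
            m = compute_metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=2))
        assert m["precision"] == 0.0

    @settings(derandomize=True, deadline=None, max_examples=200)
    @given(
        tp=st.integers(0, 500), tn=st.integers(0, 500),
        fp=st.integers(0, 500), fn=st.integers(0, 500),
    )
    def test_metric_identities(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        assert m["accuracy"] == pytest.approx((tp + tn) / (tp + tn + fp + fn))
        if tp + fp:
            assert m["precision"] == pytest.approx(tp / (tp + fp))
        if tp + fn:
            assert m["recall"] == pytest.approx(tp / (tp + fn))
        if m["precision"] + m["recall"] > 0:
            # F is the harmonic mean of precision and recall
            assert m["f_score"] == pytest.approx(
                2 / (1 / m["precision"] + 1 / m["recall"])
                if m["precision"] and m["recall"]
                else 0.0
            )

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_auroc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, 50)
        if len(np.unique(labels)) < 2:
            return
        scores = rng.random(50)
        a = roc_auc_score(labels, scores)
        b = roc_auc_score(labels, np.exp(3 * scores) - 1)
        assert a == pytest.approx(b)


class TestNestedCV:
    def test_folds_partition_and_stratify(self, small_features):
        X, y = small_features
        from sklearn.model_selection import StratifiedKFold

        outer = StratifiedKFold(n_splits=5, shuffle=True, random_state=3)
        seen = []
        for _, te in outer.split(X, y):
            seen.extend(te)
            per_class = np.bincount(y[te], minlength=2)
            assert abs(per_class[0] - per_class[1]) <= 1
        assert sorted(seen) == list(range(len(y)))

    def test_deterministic_given_seed(self, small_features):
        X, y = small_features
        kwargs = dict(
            config=FAST, outer_folds=5, inner_folds=2,
            grid=SMALL_PENALTY_GRID, seed=11,
        )
        a = nested_cv(X, y, **kwargs)
        b = nested_cv(X, y, **kwargs)
        assert a.fold_metrics == b.fold_metrics
        assert a.chosen_penalties == b.chosen_penalties

    def test_strong_motif_recovered(self, small_features):
        X, y = small_features
        report = nested_cv(
            X, y, config=FAST, outer_folds=5, inner_folds=2,
            grid=SMALL_PENALTY_GRID, seed=2,
        )
        assert report.mean["accuracy"] >= 0.9
        assert report.mean["auroc"] >= 0.95
        lo = min(m["accuracy"] for m in report.fold_metrics)
        hi = max(m["accuracy"] for m in report.fold_metrics)
        assert lo <= report.mean["accuracy"] <= hi

    def test_too_few_examples_suggests_fewer_folds(self):
        X = np.random.default_rng(0).random((8, 4))
        y = np.array([0, 1] * 4)
        with pytest.raises(ValueError, match="fewer folds"):
            nested_cv(X, y, config=FAST, outer_folds=10)

    def test_report_tsv_has_fold_rows(self, small_features):
        X, y = small_features
        report = nested_cv(
            X, y, config=FAST, outer_folds=3, inner_folds=2,
            grid=((1.12, 18.51),), seed=1,
        )
        tsv = report.to_tsv()
        lines = tsv.strip().splitlines()
        assert lines[0].startswith("fold\taccuracy")
        assert len(lines) == 1 + 3 + 2  # header + folds + mean + sd

    def test_l2_regularization_does_not_improve_training_fit(self, small_features):
        """Training-set accuracy is non-increasing (within noise) in the L2 penalty."""
        X, y = small_features
        accs = []
        for l2 in (1.0, 1000.0):
            model = train(X, y, ModelConfig(n_trees=30, max_depth=3, l2_penalty=l2))
            probs = np.array([p for p, _ in predict(model, X)])
            accs.append(np.mean((probs >= 0.5) == y))
        assert accs[1] <= accs[0] + 0.02
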