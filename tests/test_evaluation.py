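"""Splitting, classifier training, and the evaluation metric suite.

Exact metric values are checked against hand evaluation of the standard
confusion-matrix formulas through a stub model with scripted predictions.
"""

import numpy as np
import pytest

from gasfeeg import ClassifierSpec, evaluate, roc_curve, split, train
from gasfeeg.bow import FeatureTable
from gasfeeg.evaluation import FittedModel, auc_trapezoid, split_indices
from gasfeeg.exceptions import EvaluationError, RocError, SplitError, TrainingError


def _table(rows, labels, groups=None):
    return FeatureTable(rows=np.asarray(rows, float), labels=np.asarray(labels), groups=None if groups is None else np.asarray(groups))


class _ScriptedEstimator:
    """Returns pre-scripted predictions/probabilities regardless of input."""

    def __init__(self, pred, proba, classes):
        self._pred, self._proba = np.asarray(pred), np.asarray(proba)
        self.classes_ = np.asarray(classes)

    def predict(self, rows):
        return self._pred

    def predict_proba(self, rows):
        return np.column_stack([1 - self._proba, self._proba])


def _scripted_model(pred, proba, classes=("neg", "pos"), n_features=2):
    return FittedModel(
        estimator=_ScriptedEstimator(pred, proba, classes),
        spec=ClassifierSpec(kind="rf"),
        n_features=n_features,
        classes=tuple(classes),
    )


class TestSplit:
    def test_90_10_split_counts(self):
        rng = np.random.default_rng(0)
        table = _table(rng.random((4000, 5)), ["normal"] * 2000 + ["focal"] * 2000)
        train_t, test_t = split(table, test_frac=0.1, seed=0)
        assert len(train_t) == 3600
        assert len(test_t) == 400
        # stratification: both partitions balanced
        assert (test_t.labels == "focal").sum() == 200

    def test_group_split_keeps_signals_together(self):
        rng = np.random.default_rng(1)
        groups = np.repeat([f"s{i}" for i in range(100)], 40)
        labels = np.repeat(["normal", "focal"], 2000)
        table = _table(rng.random((4000, 3)), labels, groups)
        train_t, test_t = split(table, test_frac=0.1, group_by_signal=True, seed=0)
        assert len(test_t) == 400  # all epochs of 10 signals
        assert set(test_t.groups).isdisjoint(set(train_t.groups))

    def test_missing_class_raises(self):
        table = _table(np.ones((40, 2)), ["a"] * 39 + ["b"])
        with pytest.raises(SplitError):
            split(table, test_frac=0.5, stratified=False, seed=0)

    def test_deterministic_under_seed(self):
        labels = ["a"] * 50 + ["b"] * 50
        i1 = split_indices(np.array(labels), 0.2, seed=3)
        i2 = split_indices(np.array(labels), 0.2, seed=3)
        np.testing.assert_array_equal(i1[0], i2[0])

    def test_bad_fraction(self):
        with pytest.raises(SplitError):
            split_indices(np.array(["a", "b"]), test_frac=1.5)


class TestTrain:
    @pytest.fixture()
    def separable(self):
        rng = np.random.default_rng(4)
        rows = np.vstack([rng.uniform(0, 1, (20, 2)), rng.uniform(4, 5, (20, 2))])
        return _table(rows, ["neg"] * 20 + ["pos"] * 20)

    @pytest.mark.parametrize("kind", ["svm_rbf", "rf", "knn"])
    def test_separable_clouds_training_accuracy_one(self, separable, kind):
        model = train(ClassifierSpec(kind=kind, seed=0), separable)
        pred = model.estimator.predict(separable.rows)
        assert np.mean(pred == separable.labels) == 1.0

    def test_1nn_reproduces_training_labels(self, separable):
        rng = np.random.default_rng(5)
        noisy = _table(rng.random((30, 3)), rng.integers(0, 2, 30))
        model = train(ClassifierSpec(kind="knn", hyperparams={"k_neighbors": 1}), noisy)
        np.testing.assert_array_equal(model.estimator.predict(noisy.rows), noisy.labels)

    def test_rf_refit_identical_predictions(self, separable):
        rng = np.random.default_rng(6)
        probe = rng.random((10, 2)) * 5
        p1 = train(ClassifierSpec(kind="rf", seed=9), separable).estimator.predict(probe)
        p2 = train(ClassifierSpec(kind="rf", seed=9), separable).estimator.predict(probe)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError):
            train(ClassifierSpec(kind="rf"), _table(np.ones((5, 2)), ["a"] * 5))


class TestRocCurve:
    def test_perfect_ranking(self):
        pts = roc_curve([0.9, 0.8, 0.2, 0.1], ["p", "p", "n", "n"], "p")
        assert (0.0, 1.0) in pts
        assert auc_trapezoid(pts) == pytest.approx(1.0)

    def test_all_scores_equal(self):
        pts = roc_curve([0.5, 0.5, 0.5, 0.5], ["p", "p", "n", "n"], "p")
        assert pts == ((0.0, 0.0), (1.0, 1.0))
        assert auc_trapezoid(pts) == pytest.approx(0.5)

    def test_concordance_example_auc(self):
        """Scores 0.9/0.4 for positives and 0.8/0.2 for negatives: 3 of the 4
        positive-negative pairs are concordant -> AUC 0.75."""
        pts = roc_curve([0.9, 0.4, 0.8, 0.2], ["p", "p", "n", "n"], "p")
        assert auc_trapezoid(pts) == pytest.approx(0.75)

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(7)
        scores = rng.random(50)
        labels = rng.choice(["p", "n"], 50)
        pts = np.array(roc_curve(scores, labels, "p"))
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        scores = rng.random(60)
        labels = rng.choice(["p", "n"], 60)
        a1 = auc_trapezoid(roc_curve(scores, labels, "p"))
        a2 = auc_trapezoid(roc_curve(np.exp(3 * scores) - 1, labels, "p"))
        assert a1 == pytest.approx(a2)

    def test_matches_sklearn_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        scores = rng.random(80)
        labels = rng.choice([0, 1], 80)
        ours = auc_trapezoid(roc_curve(scores, labels, 1))
        assert ours == pytest.approx(roc_auc_score(labels, scores))

    def test_one_class_rejected(self):
        with pytest.raises(RocError):
            roc_curve([0.1, 0.2], ["p", "p"], "p")


class TestEvaluate:
    def _confusion_case(self, tp, fn, tn, fp):
        labels = np.array(["pos"] * (tp + fn) + ["neg"] * (tn + fp))
        pred = np.array(["pos"] * tp + ["neg"] * fn + ["neg"] * tn + ["pos"] * fp)
        # scripted probabilities consistent with predictions
        proba = np.where(pred == "pos", 0.9, 0.1)
        table = _table(np.zeros((labels.size, 2)), labels)
        model = _scripted_model(pred, proba)
        return evaluate(model, table, positive_class="pos")

    def test_perfect_classifier(self):
        rep = self._confusion_case(tp=50, fn=0, tn=50, fp=0)
        for m in ("accuracy", "precision", "recall", "specificity", "f1"):
            assert rep.metrics[m] == pytest.approx(1.0)

    def test_hand_computed_metric_suite(self):
        """TP=40, FN=10, TN=45, FP=5 under the stated formulas, to 4 d.p."""
        rep = self._confusion_case(tp=40, fn=10, tn=45, fp=5)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (40, 10, 45, 5)
        assert rep.metrics["accuracy"] == pytest.approx(0.85, abs=5e-5)
        assert rep.metrics["precision"] == pytest.approx(0.8889, abs=5e-5)
        assert rep.metrics["recall"] == pytest.approx(0.80, abs=5e-5)
        assert rep.metrics["specificity"] == pytest.approx(0.90, abs=5e-5)
        assert rep.metrics["f1"] == pytest.approx(0.8421, abs=5e-5)

    def test_f1_between_precision_and_recall(self):
        rep = self._confusion_case(tp=30, fn=20, tn=40, fp=10)
        p, r, f1 = (rep.metrics[m] for m in ("precision", "recall", "f1"))
        assert min(p, r) <= f1 <= max(p, r)

    def test_positive_class_reversal_swaps_counts_and_rates(self):
        labels = np.array(["pos"] * 50 + ["neg"] * 50)
        pred = np.concatenate([np.repeat("pos", 40), np.repeat("neg", 10),
                               np.repeat("neg", 45), np.repeat("pos", 5)])
        proba = np.where(pred == "pos", 0.9, 0.1)
        table = _table(np.zeros((100, 2)), labels)
        model = _scripted_model(pred, proba)
        a = evaluate(model, table, positive_class="pos")
        b = evaluate(model, table, positive_class="neg")
        assert (a.tp, a.fn, a.fp, a.tn) == (b.tn, b.fp, b.fn, b.tp)
        assert a.metrics["recall"] == pytest.approx(b.metrics["specificity"])
        assert a.metrics["specificity"] == pytest.approx(b.metrics["recall"])

    def test_zero_denominator_flagged(self):
        # model never predicts positive -> precision denominator zero
        rep = self._confusion_case(tp=0, fn=10, tn=10, fp=0)
        assert rep.metrics["precision"] == 0.0
        assert any("precision" in w for w in rep.warnings)

    def test_logloss_definition(self):
        labels = np.array(["pos", "neg"])
        pred = np.array(["pos", "neg"])
        proba = np.array([0.8, 0.3])
        model = _scripted_model(pred, proba)
        rep = evaluate(model, _table(np.zeros((2, 2)), labels), positive_class="pos")
        expected = -(np.log(0.8) + np.log(0.7)) / 2
        assert rep.metrics["logloss"] == pytest.approx(expected)

    def test_feature_mismatch(self):
        model = _scripted_model(["pos"], [0.9], n_features=7)
        with pytest.raises(EvaluationError):
            evaluate(model, _table(np.zeros((1, 2)), ["pos"]))

    def test_end_to_end_svm_reports_auc_and_logloss(self):
        rng = np.random.default_rng(10)
        rows = np.vstack([rng.uniform(0, 1, (40, 2)), rng.uniform(2, 3, (40, 2))])
        table = _table(rows, ["neg"] * 40 + ["pos"] * 40)
        model = train(ClassifierSpec(kind="svm_rbf", seed=0), table)
        rep = evaluate(model, table, positive_class="pos")
        assert 0.9 <= rep.metrics["auc"] <= 1.0
        assert rep.metrics["logloss"] > 0.0
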