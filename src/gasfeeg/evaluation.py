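"""Classifier training and the evaluation metric suite.

Trains RBF-kernel SVM, random forest and k-NN on BoW feature tables and
reports the full binary metric suite: accuracy, precision, recall,
specificity, F1, trapezoidal ROC AUC and log-loss, plus the confusion
counts and the ROC points themselves.

Conventions where definitions have edge cases:

* SVM ROC scores are decision-function values; SVM probabilities for
  log-loss come from Platt scaling fitted on the training data.
* A metric with a zero denominator is reported as 0.0 and flagged in
  ``EvaluationReport.warnings`` rather than dropped.
* Log-loss probabilities are clipped to [1e-15, 1 - 1e-15].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .bow import FeatureTable
from .exceptions import (
    ConfigError,
    EvaluationError,
    RocError,
    SplitError,
    TrainingError,
)

__all__ = [
    "ClassifierSpec",
    "FittedModel",
    "EvaluationReport",
    "split",
    "split_indices",
    "train",
    "evaluate",
    "roc_curve",
    "auc_trapezoid",
]

_KINDS = ("svm_rbf", "rf", "knn")


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier and its hyperparameters.

    Defaults (used where no value is configured): SVM C=1, gamma scaled by
    1/(n_features * feature variance); RF 100 trees, unlimited depth; k-NN
    with 5 neighbours.
    """

    kind: str = "rf"
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigError(f"classifier kind must be one of {_KINDS}, got {self.kind!r}")

    def build(self):
        hp = dict(self.hyperparams)
        if self.kind == "svm_rbf":
            return SVC(
                kernel="rbf",
                C=hp.get("C", 1.0),
                gamma=hp.get("gamma", "scale"),
                random_state=self.seed,
            )
        if self.kind == "rf":
            return RandomForestClassifier(
                n_estimators=hp.get("n_trees", 100),
                max_depth=hp.get("max_depth", None),
                random_state=self.seed,
            )
        return KNeighborsClassifier(n_neighbors=hp.get("k_neighbors", 5))


@dataclass(frozen=True)
class FittedModel:
    """Opaque fitted estimator plus the metadata needed to reapply it."""

    estimator: object
    spec: ClassifierSpec
    n_features: int
    classes: tuple
    feature_idx: np.ndarray | None = None
    platt: object | None = None  # sigmoid calibrator for SVM probabilities

    def scores(self, rows: np.ndarray, positive_class) -> np.ndarray:
        """Ranking scores for ROC: decision function for SVM, else P(positive)."""
        pos_col = list(self.classes).index(positive_class)
        if self.spec.kind == "svm_rbf":
            dec = self.estimator.decision_function(rows)
            # decision_function is oriented toward classes_[1]
            return dec if pos_col == 1 else -dec
        return self.estimator.predict_proba(rows)[:, pos_col]

    def probabilities(self, rows: np.ndarray, positive_class) -> np.ndarray:
        pos_col = list(self.classes).index(positive_class)
        if self.spec.kind == "svm_rbf":
            dec = self.estimator.decision_function(rows).reshape(-1, 1)
            return self.platt.predict_proba(dec)[:, pos_col]
        return self.estimator.predict_proba(rows)[:, pos_col]


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts, metric suite and ROC points for one model."""

    tp: int
    fp: int
    tn: int
    fn: int
    metrics: dict
    roc_points: tuple[tuple[float, float], ...]
    positive_class: str
    warnings: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "metrics": self.metrics,
            "roc_points": [list(p) for p in self.roc_points],
            "positive_class": str(self.positive_class),
            "warnings": list(self.warnings),
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path


def split_indices(
    labels: np.ndarray,
    test_frac: float = 0.1,
    stratified: bool = True,
    groups: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified (optionally grouped) train/test row indices.

    With ``groups`` set, all rows of a group land on the same side; groups
    are stratified by their (single) label.
    """
    if not 0 < test_frac < 1:
        raise SplitError(f"test_frac must be in (0, 1), got {test_frac}")
    labels = np.asarray(labels)
    idx = np.arange(labels.size)
    if groups is not None:
        groups = np.asarray(groups)
        uniq, first = np.unique(groups, return_index=True)
        group_labels = labels[first]
        for g in uniq:
            if np.unique(labels[groups == g]).size > 1:
                raise SplitError(f"group {g!r} spans multiple labels")
        tr_g, te_g = train_test_split(
            uniq,
            test_size=test_frac,
            stratify=group_labels if stratified else None,
            random_state=seed,
        )
        train_idx = idx[np.isin(groups, tr_g)]
        test_idx = idx[np.isin(groups, te_g)]
    else:
        train_idx, test_idx = train_test_split(
            idx,
            test_size=test_frac,
            stratify=labels if stratified else None,
            random_state=seed,
        )
    for name, part in (("train", train_idx), ("test", test_idx)):
        present = np.unique(labels[part])
        if present.size < np.unique(labels).size:
            raise SplitError(f"a class is absent from the {name} partition")
    return np.sort(train_idx), np.sort(test_idx)


def split(
    table: FeatureTable,
    test_frac: float = 0.1,
    stratified: bool = True,
    group_by_signal: bool = False,
    seed: int = 0,
) -> tuple[FeatureTable, FeatureTable]:
    """Partition a feature table into train and test tables."""
    groups = table.groups if group_by_signal else None
    if group_by_signal and groups is None:
        raise SplitError("group_by_signal requested but the table has no groups")
    tr, te = split_indices(table.labels, test_frac, stratified, groups, seed)
    return table.subset(tr), table.subset(te)


def train(spec: ClassifierSpec, train_table: FeatureTable) -> FittedModel:
    """Fit one classifier on a feature table (deterministic under spec.seed)."""
    classes = np.unique(train_table.labels)
    if classes.size < 2:
        raise TrainingError("training requires at least two classes")
    if not np.all(np.isfinite(train_table.rows)):
        raise TrainingError("training table contains non-finite values")
    est = spec.build()
    est.fit(train_table.rows, train_table.labels)
    platt = None
    if spec.kind == "svm_rbf":
        # Platt scaling: logistic fit on training decision values
        from sklearn.linear_model import LogisticRegression

        dec = est.decision_function(train_table.rows).reshape(-1, 1)
        platt = LogisticRegression(C=1e6, random_state=spec.seed)
        platt.fit(dec, train_table.labels)
    return FittedModel(
        estimator=est,
        spec=spec,
        n_features=train_table.n_features,
        classes=tuple(est.classes_),
        feature_idx=train_table.selected_idx,
        platt=platt,
    )


def roc_curve(
    scores: Sequence[float], labels: Sequence, positive_class
) -> tuple[tuple[float, float], ...]:
    """ROC points (FPR, TPR) swept over the distinct scores, descending.

    The curve starts at (0, 0), ends at (1, 1), is nondecreasing in both
    coordinates, and duplicate points are removed.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise RocError("ROC requires at least one positive and one negative")
    points = [(0.0, 0.0)]
    for t in np.unique(scores)[::-1]:
        pred = scores >= t
        tpr = float((pred & pos).sum() / n_pos)
        fpr = float((pred & ~pos).sum() / n_neg)
        if (fpr, tpr) != points[-1]:
            points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return tuple(points)


def auc_trapezoid(roc_points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under a (FPR, TPR) staircase."""
    pts = np.asarray(roc_points, dtype=np.float64)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def evaluate(
    model: FittedModel, test_table: FeatureTable, positive_class: str | None = None
) -> EvaluationReport:
    """Evaluate a fitted model on a held-out table.

    Metrics follow the standard confusion-matrix definitions; AUC is the
    trapezoidal area under the score-threshold ROC; log-loss uses clipped
    positive-class probabilities.
    """
    if len(test_table) == 0:
        raise EvaluationError("test table is empty")
    if test_table.n_features != model.n_features:
        raise EvaluationError(
            f"model expects {model.n_features} features, table has {test_table.n_features}"
        )
    if positive_class is None:
        positive_class = model.classes[-1]
    if positive_class not in model.classes:
        raise EvaluationError(f"positive class {positive_class!r} unknown to the model")

    pred = model.estimator.predict(test_table.rows)
    truth = test_table.labels
    pos_t = truth == positive_class
    pos_p = pred == positive_class
    tp = int((pos_p & pos_t).sum())
    fp = int((pos_p & ~pos_t).sum())
    fn = int((~pos_p & pos_t).sum())
    tn = int((~pos_p & ~pos_t).sum())

    warnings: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.append(f"{name} denominator is zero; reported as 0")
            return 0.0
        return num / den

    acc = ratio(tp + tn, tp + tn + fp + fn, "accuracy")
    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    specificity = ratio(tn, tn + fp, "specificity")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")

    scores = model.scores(test_table.rows, positive_class)
    points = roc_curve(scores, truth, positive_class)
    auc = auc_trapezoid(points)

    p = np.clip(model.probabilities(test_table.rows, positive_class), 1e-15, 1 - 1e-15)
    y = pos_t.astype(np.float64)
    logloss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    return EvaluationReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        metrics={
            "accuracy": acc,
            "precision": precision,
            "recall": recall,
            "specificity": specificity,
            "f1": f1,
            "auc": auc,
            "logloss": logloss,
        },
        roc_points=points,
        positive_class=str(positive_class),
        warnings=tuple(warnings),
    )
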