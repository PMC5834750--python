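"""Group classification from global network metric AUCs.

A boosted ensemble of shallow decision trees (multiclass SAMME
AdaBoost, 100 learning cycles, depth-1 stumps by default) predicts
each subject's group from the four global metric AUCs (Cp, Lp, Eg,
Eloc).  Generalization is estimated with leave-one-out
cross-validation; per-class sensitivity and specificity come from the
aggregated one-vs-rest confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.tree import DecisionTreeClassifier

DEFAULT_ROUNDS = 100
DEFAULT_DEPTH = 1
FEATURES = ("AUC_Cp", "AUC_Lp", "AUC_Eg", "AUC_Eloc")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows = true class, columns = predicted
    classes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix shape must match class list")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"true_{c}" for c in self.classes],
            columns=[f"pred_{c}" for c in self.classes],
        )


def _as_features(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        cols = [c for c in FEATURES if c in features.columns] or list(features.columns)
        return features[cols].to_numpy(dtype=float)
    return np.asarray(features, dtype=float)


def adaboost_fit(
    features,
    labels: Sequence[str],
    n_rounds: int = DEFAULT_ROUNDS,
    tree_depth: int = DEFAULT_DEPTH,
    seed: int | None = 0,
) -> AdaBoostClassifier:
    """Fit the boosted-stump classifier (SAMME multiclass weighting)."""
    x = _as_features(features)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to fit a classifier")
    if len(y) < 4:
        raise ValueError("need at least 4 subjects")
    model = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=tree_depth, random_state=seed),
        n_estimators=n_rounds,
        random_state=seed,
    )
    model.fit(x, y)
    return model


def loocv(
    features,
    labels: Sequence[str],
    n_rounds: int = DEFAULT_ROUNDS,
    tree_depth: int = DEFAULT_DEPTH,
    seed: int | None = 0,
) -> tuple[np.ndarray, ConfusionMatrix, float]:
    """Leave-one-out cross-validation.

    Each subject is predicted by a model trained on all others; the
    confusion matrix aggregates the held-out predictions.  If a
    training fold loses an entire class, that fold simply predicts
    among the remaining classes.
    """
    x = _as_features(features)
    y = np.asarray(labels)
    n = len(y)
    if n < 4:
        raise ValueError("LOOCV needs at least 4 subjects")
    classes = sorted(np.unique(y).tolist())
    preds = np.empty(n, dtype=object)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = adaboost_fit(x[mask], y[mask], n_rounds, tree_depth, seed)
        preds[i] = model.predict(x[i : i + 1])[0]
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    idx = {c: k for k, c in enumerate(classes)}
    for true, pred in zip(y, preds):
        counts[idx[true], idx[pred]] += 1
    cm = ConfusionMatrix(counts, classes)
    return preds, cm, cm.accuracy


def sensitivity_specificity(
    cm: ConfusionMatrix, positive_class: str
) -> tuple[float, float]:
    """One-vs-rest sensitivity and specificity for one class.

    sensitivity = TP / (TP + FN); specificity = TN / (TN + FP).
    Undefined ratios (zero denominator) are returned as NaN.
    """
    if positive_class not in cm.classes:
        raise ValueError(f"class {positive_class!r} not in confusion matrix")
    k = cm.classes.index(positive_class)
    tp = cm.counts[k, k]
    fn = cm.counts[k].sum() - tp
    fp = cm.counts[:, k].sum() - tp
    tn = cm.counts.sum() - tp - fn - fp
    sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return float(sens), float(spec)


def classification_report(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class one-vs-rest sensitivity/specificity table."""
    rows = []
    for c in cm.classes:
        sens, spec = sensitivity_specificity(cm, c)
        rows.append({"class": c, "sensitivity": sens, "specificity": spec})
    return pd.DataFrame(rows)
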