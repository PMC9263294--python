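"""Classification metrics, ROC/AUC, NRI/IDI, and baseline classifiers.

The positive class is death (label 1) throughout, so sensitivity is the
death recall rate.  ROC uses the standard false-positive rate
FP / (FP + TN) on the x-axis.  Model comparison uses the two-category net
reclassification improvement (NRI) at a probability cut (default 0.5) and
the integrated discrimination improvement (IDI).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "classification_metrics",
    "roc_auc",
    "reclassification_metrics",
    "baseline_suite",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    sensitivity: float | None
    specificity: float | None
    accuracy: float
    f1: float | None
    counts: ConfusionCounts
    auc: float | None = None
    nri: float | None = None
    idi: float | None = None
    feature_importances: np.ndarray | None = None


def classification_metrics(labels: np.ndarray, predicted: np.ndarray) -> MetricsReport:
    """Confusion counts plus sensitivity TP/(TP+FN), specificity TN/(TN+FP),
    accuracy and F1.  With no positive labels present, sensitivity and F1
    are undefined (None), not silently zero.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    acc = (tp + tn) / counts.n
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else None
    return MetricsReport(sensitivity=sens, specificity=spec, accuracy=acc, f1=f1, counts=counts)


def roc_auc(labels: np.ndarray, death_probabilities: np.ndarray) -> tuple[pd.DataFrame, float]:
    """ROC points (threshold, FPr, TPr) and trapezoid AUC.

    FPr = FP/(FP+TN), TPr = TP/(TP+FN); requires both classes present.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(death_probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    fpr, tpr, thr = skmetrics.roc_curve(y, p)
    auc = float(skmetrics.auc(fpr, tpr))
    points = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return points, auc


def reclassification_metrics(
    labels: np.ndarray,
    probs_reference: np.ndarray,
    probs_new: np.ndarray,
    cut: float = 0.5,
) -> tuple[float, float]:
    """Two-category NRI at ``cut`` and IDI of a new model vs a reference.

    NRI = [P(up | event) - P(down | event)] + [P(down | nonevent) - P(up | nonevent)]
    where up/down means crossing the cut upward/downward when moving from
    the reference to the new probabilities.

    IDI = (mean new - mean reference prob among events)
        - (mean new - mean reference prob among nonevents).
    """
    y = np.asarray(labels, dtype=int)
    pr = np.asarray(probs_reference, dtype=float)
    pn = np.asarray(probs_new, dtype=float)
    if not (0.0 < cut < 1.0):
        raise ValueError("cut must be in (0, 1)")
    events = y == 1
    if events.all() or (~events).all():
        raise ValueError("both classes must be present")
    up = (pr <= cut) & (pn > cut)
    down = (pr > cut) & (pn <= cut)
    nri = (up[events].mean() - down[events].mean()) + (
        down[~events].mean() - up[~events].mean()
    )
    idi = (pn[events].mean() - pr[events].mean()) - (
        pn[~events].mean() - pr[~events].mean()
    )
    return float(nri), float(idi)


_BASELINES = {
    "decision_tree": lambda seed: DecisionTreeClassifier(random_state=seed),
    "random_forest": lambda seed: RandomForestClassifier(random_state=seed),
    "gradient_boosting": lambda seed: GradientBoostingClassifier(random_state=seed),
    "knn": lambda seed: KNeighborsClassifier(),
    "svm": lambda seed: SVC(probability=True, random_state=seed),
    "logistic_regression": lambda seed: LogisticRegression(max_iter=2000, random_state=seed),
}


def baseline_suite(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    test_y: np.ndarray,
    seed: int = 0,
) -> dict[str, MetricsReport | dict]:
    """Fit the six standard comparison classifiers and report their metrics.

    Decision tree, random forest, gradient boosting, k-nearest neighbors,
    SVM and logistic regression at library defaults with fixed seeds.  Tree
    models additionally report feature importances.  A classifier that
    fails on a degenerate training set contributes an error record instead
    of aborting the suite.
    """
    out: dict[str, MetricsReport | dict] = {}
    for name, factory in _BASELINES.items():
        try:
            clf = factory(seed)
            clf.fit(train_x, train_y)
            pred = clf.predict(test_x)
            rep = classification_metrics(test_y, pred)
            if hasattr(clf, "predict_proba") and len(np.unique(test_y)) == 2:
                _, rep.auc = roc_auc(test_y, clf.predict_proba(test_x)[:, 1])
            if hasattr(clf, "feature_importances_"):
                rep.feature_importances = clf.feature_importances_
            out[name] = rep
        except Exception as exc:  # degenerate input: record and continue
            out[name] = {"error": f"{type(exc).__name__}: {exc}"}
    return out


def report_to_dict(rep: MetricsReport) -> dict:
    d = {
        "sensitivity": rep.sensitivity,
        "specificity": rep.specificity,
        "accuracy": rep.accuracy,
        "f1": rep.f1,
        "auc": rep.auc,
        "nri": rep.nri,
        "idi": rep.idi,
        "tp": rep.counts.tp,
        "tn": rep.counts.tn,
        "fp": rep.counts.fp,
        "fn": rep.counts.fn,
    }
    return {k: v for k, v in d.items() if v is not None}
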