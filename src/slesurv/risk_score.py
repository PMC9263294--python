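"""Logistic-regression survival-risk score with a zero survival threshold.

A logistic regression fitted on the 1:1 under-sampled labeled data yields
per-feature risk coefficients w (positive: the feature pushes toward
death).  Each patient's risk score is the linear predictor

    z = w0*x0 + w1*x1 + ... + wn*xn        (x0 = 1, the intercept term)

and outcomes are classified against a survival threshold T (default 0):
z > T predicts death, z <= T predicts survival.  Because the intercept is
part of z, the zero threshold coincides exactly with the logistic
0.5-probability decision boundary, which is why the score scatter shows a
clear dividing line at zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

__all__ = [
    "RiskModel",
    "fit_risk_model",
    "risk_score",
    "classify_by_threshold",
    "threshold_separation_report",
]


@dataclass
class RiskModel:
    """coefficients[0] is the intercept w0; the rest align with feature_names."""

    coefficients: np.ndarray
    feature_names: list[str]
    threshold: float = 0.0
    separation_flagged: bool = False

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "coefficients": self.coefficients.tolist(),
                    "feature_names": self.feature_names,
                    "threshold": self.threshold,
                    "separation_flagged": self.separation_flagged,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        d = json.loads(Path(path).read_text())
        return cls(
            coefficients=np.array(d["coefficients"]),
            feature_names=d["feature_names"],
            threshold=d["threshold"],
            separation_flagged=d["separation_flagged"],
        )


def fit_risk_model(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.0,
) -> RiskModel:
    """Maximum-likelihood logistic regression on balanced labeled data.

    Fits an (effectively) unpenalized logistic regression; if the data are
    perfectly separated the MLE diverges, so the fit falls back to a mild
    ridge penalty and the model is flagged.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        names = [f"x{i + 1}" for i in range(x.shape[1])]
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    # near-MLE fit: very weak penalty for numerical stability
    clf = LogisticRegression(C=1e6, max_iter=5000)
    clf.fit(x, y)
    coefs = np.concatenate([clf.intercept_, clf.coef_[0]])
    flagged = False
    if np.all(clf.predict(x) == y):
        # zero training error means a separating hyperplane exists, so the
        # true MLE diverges: cap the coefficients via a mild ridge and flag
        flagged = True
        clf = LogisticRegression(C=1.0, max_iter=5000)
        clf.fit(x, y)
        coefs = np.concatenate([clf.intercept_, clf.coef_[0]])
    return RiskModel(
        coefficients=coefs,
        feature_names=names,
        threshold=threshold,
        separation_flagged=flagged,
    )


def risk_score(model: RiskModel, features: pd.DataFrame | np.ndarray) -> np.ndarray:
    """z = w^T x with x0 = 1: the per-patient survival-risk score."""
    if isinstance(features, pd.DataFrame):
        x = features[model.feature_names].to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
    if x.shape[1] != len(model.coefficients) - 1:
        raise ValueError(
            f"feature length {x.shape[1]} != model's {len(model.coefficients) - 1}"
        )
    return model.intercept + x @ model.coefficients[1:]


def classify_by_threshold(scores: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """z > T -> death (1); z <= T -> survival (0).

    The boundary case z = T goes to survival, completing the two strict
    inequalities of the decision rule deterministically.  At T = 0 this is
    exactly the logistic 0.5-probability rule.
    """
    z = np.asarray(scores, dtype=float)
    return (z > threshold).astype(int)


def threshold_separation_report(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.0
) -> dict:
    """Per-class score quartiles plus the threshold-crossing counts.

    Crossings are the survivors scoring above T and the deaths scoring at
    or below T — the outliers relative to the survival threshold.
    """
    z = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    out = {"threshold": threshold}
    for cls, name in ((0, "survival"), (1, "death")):
        zi = z[y == cls]
        q1, q2, q3 = np.percentile(zi, [25, 50, 75])
        out[name] = {
            "n": int(zi.size),
            "min": float(zi.min()),
            "q1": float(q1),
            "median": float(q2),
            "q3": float(q3),
            "max": float(zi.max()),
        }
    surv_above = int(np.sum((y == 0) & (z > threshold)))
    dead_below = int(np.sum((y == 1) & (z <= threshold)))
    out["survivors_above_threshold"] = surv_above
    out["deaths_below_threshold"] = dead_below
    out["crossing_fraction_survival"] = surv_above / int(np.sum(y == 0))
    out["crossing_fraction_death"] = dead_below / int(np.sum(y == 1))
    return out
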