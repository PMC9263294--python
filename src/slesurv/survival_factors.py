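"""Survival-factor analysis: LASSO screening, forward-stepwise Cox, and
Kaplan-Meier curves.

Features are first screened with an L1-penalized logistic regression on
the survival outcome (regularization strength chosen by cross-validation),
then the surviving features enter a forward-stepwise Cox
proportional-hazards model (likelihood-ratio entry p < 0.05, removal
p > 0.10, at most 20 steps).  Univariate survival curves use the
Kaplan-Meier product-limit estimator.  Only followed (labeled) records
enter the survival models; survivors contribute censoring times at the
follow-up horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LassoResult",
    "CoxResult",
    "KMCurve",
    "lasso_select",
    "stepwise_cox",
    "km_estimate",
]


@dataclass
class LassoResult:
    selected: list[str]
    coefficients: pd.Series
    chosen_lambda: float
    cv_grid: np.ndarray
    cv_scores: np.ndarray  # mean CV log-loss per grid point


def lasso_select(
    features: pd.DataFrame,
    labels: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> LassoResult:
    """L1-penalized logistic screening of the outcome-associated features.

    ``lambda_grid`` is the per-sample L1 penalty strength (the sklearn
    ``C`` is its reciprocal scaled by n).  The grid point with the lowest
    mean cross-validated log-loss wins; features with nonzero coefficients
    at that lambda are returned.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; nothing to screen")
    x = features.to_numpy(dtype=float)
    n = x.shape[0]
    if n < cv_folds:
        raise ValueError("need at least cv_folds records")
    if lambda_grid is None:
        lambda_grid = np.logspace(-4, -0.5, 25)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0 or np.any(lambda_grid <= 0):
        raise ValueError("lambda grid must be nonempty and positive")

    def _fit(xtr, ytr, lam):
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (len(ytr) * lam), solver="liblinear", max_iter=5000
        )
        clf.fit(xtr, ytr)
        return clf

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    scores = np.zeros(lambda_grid.size)
    eps = 1e-12
    for tr, te in skf.split(x, y):
        for i, lam in enumerate(lambda_grid):
            clf = _fit(x[tr], y[tr], lam)
            p = np.clip(clf.predict_proba(x[te])[:, 1], eps, 1 - eps)
            scores[i] += -np.mean(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))
    scores /= cv_folds
    best = int(np.argmin(scores))
    lam = float(lambda_grid[best])
    clf = _fit(x, y, lam)
    coefs = pd.Series(clf.coef_[0], index=features.columns)
    selected = coefs.index[coefs != 0.0].tolist()
    return LassoResult(
        selected=selected,
        coefficients=coefs,
        chosen_lambda=lam,
        cv_grid=lambda_grid,
        cv_scores=scores,
    )


@dataclass
class CoxResult:
    variables: list[str]
    summary: pd.DataFrame  # coef, hazard_ratio, ci_lower, ci_upper, p
    step_log: list[dict] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return len(self.step_log)


def _cox_loglik(df: pd.DataFrame, covariates: list[str]) -> float:
    if not covariates:
        # null log partial likelihood (all betas 0) under Efron ties,
        # matching the likelihood lifelines maximizes
        t = df["time"].to_numpy()
        e = df["event"].to_numpy().astype(bool)
        ll = 0.0
        for et in np.unique(t[e]):
            n_risk = int(np.sum(t >= et))
            d = int(np.sum(e & (t == et)))
            ll -= sum(np.log(n_risk - l) for l in range(d))
        return float(ll)
    cph = CoxPHFitter(penalizer=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df[["time", "event", *covariates]], duration_col="time", event_col="event")
    return float(cph.log_likelihood_)


def stepwise_cox(
    features: pd.DataFrame,
    outcome: np.ndarray,
    time: np.ndarray,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    max_steps: int = 20,
) -> CoxResult:
    """Forward-stepwise Cox proportional-hazards selection.

    At each step the candidate with the smallest likelihood-ratio p-value
    below ``entry_p`` enters; any included variable whose LR p-value (for
    dropping it from the current model) exceeds ``removal_p`` is removed.
    Stops when no candidate can enter or after ``max_steps`` steps.  An
    empty model (nothing passes entry) is a valid result, not an error.
    """
    y = np.asarray(outcome, dtype=int)
    t = np.asarray(time, dtype=float)
    if y.sum() == 0:
        raise ValueError("need at least one event")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    df = features.copy()
    df["time"] = t
    df["event"] = y
    candidates = [c for c in features.columns if features[c].nunique() > 1]
    included: list[str] = []
    step_log: list[dict] = []
    ll_current = _cox_loglik(df, included)

    for step in range(max_steps):
        best_name, best_p, best_ll = None, None, None
        for c in candidates:
            if c in included:
                continue
            try:
                ll_new = _cox_loglik(df, included + [c])
            except Exception:
                continue
            lr = 2.0 * (ll_new - ll_current)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            if p < entry_p and (best_p is None or p < best_p):
                best_name, best_p, best_ll = c, p, ll_new
        if best_name is None:
            break
        included.append(best_name)
        ll_current = best_ll
        step_log.append({"step": step + 1, "action": "enter", "variable": best_name, "p": best_p})

        # backward sweep: drop variables that no longer earn their place
        removed = True
        while removed and len(included) > 1:
            removed = False
            worst_name, worst_p = None, None
            for c in included:
                ll_without = _cox_loglik(df, [v for v in included if v != c])
                lr = 2.0 * (ll_current - ll_without)
                p = float(stats.chi2.sf(max(lr, 0.0), df=1))
                if p > removal_p and (worst_p is None or p > worst_p):
                    worst_name, worst_p = c, p
            if worst_name is not None and worst_name != best_name:
                included.remove(worst_name)
                ll_current = _cox_loglik(df, included)
                step_log.append(
                    {"step": step + 1, "action": "remove", "variable": worst_name, "p": worst_p}
                )
                removed = True

    if not included:
        empty = pd.DataFrame(
            columns=["coef", "hazard_ratio", "ci_lower", "ci_upper", "p"]
        )
        return CoxResult(variables=[], summary=empty, step_log=step_log)

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df[["time", "event", *included]], duration_col="time", event_col="event")
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hazard_ratio": s["exp(coef)"],
            "ci_lower": np.exp(s["coef lower 95%"]),
            "ci_upper": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    return CoxResult(variables=included, summary=summary, step_log=step_log)


@dataclass
class KMCurve:
    group: str
    event_times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_at_risk": self.at_risk,
                "survival": self.survival,
            }
        )


def km_estimate(
    time: np.ndarray,
    event: np.ndarray,
    group: np.ndarray | None = None,
) -> dict[str, KMCurve]:
    """Kaplan-Meier product-limit curves, one per group.

    S(t) = prod over event times t_j <= t of (1 - d_j / n_j); censored
    records leave the risk set without contributing an event.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    if group is None:
        group = np.array(["all"] * len(t))
    group = np.asarray(group)
    curves: dict[str, KMCurve] = {}
    for g in pd.unique(group):
        mask = group == g
        if not mask.any():
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], event_observed=e[mask])
        ev_times = np.sort(np.unique(t[mask][e[mask] == 1]))
        surv = kmf.survival_function_at_times(ev_times).to_numpy()
        at_risk = np.array([int(np.sum(t[mask] >= et)) for et in ev_times])
        curves[str(g)] = KMCurve(
            group=str(g), event_times=ev_times, at_risk=at_risk, survival=surv
        )
    return curves
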