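"""Root-cause analysis of the outcome classifier by repeated retraining.

The classifier is retrained R times (different seeds and different
under-sampling draws) and each validation record's *wrong judgment rate*
(WJR) — the fraction of runs whose prediction disagrees with its true
label — is computed.  Records are partitioned by WJR into:

* TNG: survivors consistently judged survival (WJR < 0.25)
* FPG: survivors consistently judged death (WJR > 0.75)
* TPG: deaths consistently judged death (WJR < 0.25)
* FNG: deaths consistently judged survival (WJR > 0.75)
* other: everything with WJR between the bounds (inclusive)

For each feature the per-group effective proportion (Fep: prevalence for
binary features, mean for continuous) feeds the *death threat
coefficient*:

    Dtc(FPG-TNG) = Fep_FPG / Fep_TNG
    Dtc(TPG-FNG) = Fep_TPG / Fep_FNG

The higher the Dtc, the greater the feature's threat to death; a feature
with both ratios at or above the flag threshold (default 1.5) is flagged
as death-associated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WJRTable",
    "SubgroupPartition",
    "DtcReport",
    "compute_wjr",
    "assign_subgroups",
    "effective_proportion",
    "death_threat_coefficient",
]

GROUPS = ("TNG", "FPG", "TPG", "FNG")


@dataclass
class WJRTable:
    record_ids: np.ndarray
    true_labels: np.ndarray
    predictions: np.ndarray  # (n, R)
    wjr: np.ndarray

    @property
    def n_runs(self) -> int:
        return self.predictions.shape[1]


@dataclass
class SubgroupPartition:
    assignment: np.ndarray  # strings in GROUPS + ("other",)

    def members(self, group: str) -> np.ndarray:
        return np.where(self.assignment == group)[0]

    def counts(self) -> dict[str, int]:
        return {g: int(np.sum(self.assignment == g)) for g in GROUPS + ("other",)}


def compute_wjr(true_labels: np.ndarray, prediction_matrix: np.ndarray) -> WJRTable:
    """Per-record fraction of the R runs that misjudged the record."""
    y = np.asarray(true_labels, dtype=int)
    preds = np.asarray(prediction_matrix, dtype=int)
    if preds.ndim != 2 or preds.shape[1] == 0:
        raise ValueError("prediction matrix must be n x R with R >= 1")
    if preds.shape[0] != y.shape[0]:
        raise ValueError("label / prediction row mismatch")
    wjr = np.mean(preds != y[:, None], axis=1)
    return WJRTable(
        record_ids=np.arange(y.shape[0]), true_labels=y, predictions=preds, wjr=wjr
    )


def assign_subgroups(table: WJRTable, lo: float = 0.25, hi: float = 0.75) -> SubgroupPartition:
    """Partition records into TNG/FPG/TPG/FNG/other by WJR.

    The inequalities are strict: records with lo <= WJR <= hi fall in
    "other".
    """
    if lo >= hi:
        raise ValueError("need lo < hi")
    out = np.full(table.wjr.shape[0], "other", dtype=object)
    surv = table.true_labels == 0
    dead = table.true_labels == 1
    out[surv & (table.wjr < lo)] = "TNG"
    out[surv & (table.wjr > hi)] = "FPG"
    out[dead & (table.wjr < lo)] = "TPG"
    out[dead & (table.wjr > hi)] = "FNG"
    return SubgroupPartition(assignment=np.asarray(out))


def effective_proportion(
    feature_values: np.ndarray, group_indices: np.ndarray
) -> float | None:
    """Fep of one feature in one group: prevalence if binary, mean otherwise.

    An empty group has no defined Fep (returns None).
    """
    idx = np.asarray(group_indices, dtype=int)
    if idx.size == 0:
        return None
    vals = np.asarray(feature_values, dtype=float)[idx]
    return float(np.mean(vals))


@dataclass
class DtcReport:
    table: pd.DataFrame  # feature, fep per group, two ratios, flagged

    def flagged_features(self) -> list[str]:
        return self.table.loc[self.table["flagged"], "feature"].tolist()


def death_threat_coefficient(
    features: pd.DataFrame,
    partition: SubgroupPartition,
    flag_threshold: float = 1.5,
) -> DtcReport:
    """Per-feature death threat coefficients over a WJR partition.

    Dtc(FPG-TNG) = Fep_FPG / Fep_TNG and Dtc(TPG-FNG) = Fep_TPG / Fep_FNG;
    a feature is flagged when both ratios are >= ``flag_threshold``.  A
    zero or undefined denominator leaves that ratio NaN and the feature
    unflagged, with a warning.
    """
    groups = {g: partition.members(g) for g in GROUPS}
    rows = []
    for name in features.columns:
        vals = features[name].to_numpy(dtype=float)
        fep = {g: effective_proportion(vals, groups[g]) for g in GROUPS}

        def _ratio(num_g: str, den_g: str) -> float:
            num, den = fep[num_g], fep[den_g]
            if num is None or den is None or den == 0.0:
                warnings.warn(
                    f"feature {name!r}: Dtc {num_g}/{den_g} undefined (empty group or zero Fep)"
                )
                return float("nan")
            return num / den

        d1 = _ratio("FPG", "TNG")
        d2 = _ratio("TPG", "FNG")
        flagged = (
            np.isfinite(d1) and np.isfinite(d2) and d1 >= flag_threshold and d2 >= flag_threshold
        )
        rows.append(
            {
                "feature": name,
                "fep_tng": fep["TNG"],
                "fep_fpg": fep["FPG"],
                "fep_tpg": fep["TPG"],
                "fep_fng": fep["FNG"],
                "dtc_fpg_tng": d1,
                "dtc_tpg_fng": d2,
                "flagged": bool(flagged),
            }
        )
    return DtcReport(table=pd.DataFrame(rows))


def repeated_prediction_matrix(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    censored_features: np.ndarray,
    eval_features: np.ndarray,
    n_runs: int = 20,
    net_cfg=None,
    loss_cfg=None,
    seed: int = 0,
    semi_supervised: bool = True,
) -> np.ndarray:
    """Predictions of ``n_runs`` independently retrained classifiers.

    Each run reseeds both the under-sampling draw and the network training
    (initialization and batch order).  With ``semi_supervised`` the full
    four-step scheme runs per run (supervised warm-up, pseudo-labeling of
    the censored records, cost-sensitive retraining); otherwise only the
    supervised model is trained.
    """
    import dataclasses

    from .cssnn import NetConfig, pseudo_label, train_cost_sensitive, train_initial
    from .data_model import undersample_majority

    net_cfg = net_cfg or NetConfig()
    root = np.random.default_rng(seed)
    preds = np.empty((eval_features.shape[0], n_runs), dtype=int)
    for r in range(n_runs):
        sub_seed = int(root.integers(2**31))
        keep = undersample_majority(train_labels, seed=sub_seed)
        cfg_r = dataclasses.replace(net_cfg, seed=sub_seed)
        model = train_initial(train_features[keep], train_labels[keep], cfg_r)
        if semi_supervised and censored_features.shape[0] > 0:
            pseudo = pseudo_label(model, censored_features)
            model = train_cost_sensitive(
                train_features, train_labels, censored_features, pseudo, cfg_r, loss_cfg
            )
        preds[:, r] = model.predict(eval_features)
    return preds
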