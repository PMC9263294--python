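"""End-to-end orchestration of the survival-analysis scheme.

One :func:`run_pipeline` call executes, in order: cohort simulation (or
CSV load), normalization, stratified splitting, majority under-sampling,
the four-step cost-sensitive semi-supervised training, evaluation against
the baseline classifiers, WJR/Dtc root-cause analysis, LASSO screening +
stepwise Cox + Kaplan-Meier curves, and the logistic survival-risk score.
Every stage writes its report (CSV/JSON) into the output directory and
appends a structured line to ``run_log.json``; the whole run is a pure
function of the config and its seed.
"""

from __future__ import annotations

import dataclasses
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_stats, evaluation, risk_score, root_cause, survival_factors
from .cssnn import LossConfig, NetConfig, pseudo_label, train_cost_sensitive, train_initial
from .data_model import normalize_frame, split_cohort, undersample_majority
from .synthetic_cohort import (
    Cohort,
    CohortSpec,
    default_spec,
    generate_cohort,
    read_cohort_csv,
    write_cohort_csv,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    cohort_csv: str | None = None  # None -> simulate
    cohort_spec: CohortSpec | None = None
    train_ratio: float = 0.8
    seed: int = 0
    net: NetConfig = field(default_factory=NetConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    wjr_runs: int = 20
    dtc_threshold: float = 1.5
    risk_threshold: float = 0.0
    lasso_grid: np.ndarray | None = None
    outdir: str = "slesurv_run"


def _log(log: list[dict], outdir: Path, stage: str, t0: float, **info) -> None:
    log.append({"stage": stage, "seconds": round(_time.time() - t0, 3), **info})
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))


def run_pipeline(config: RunConfig) -> Path:
    """Run the full scheme; returns the artifact directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    rng = np.random.default_rng(config.seed)

    def stage(name):
        t0 = _time.time()

        def done(**info):
            _log(log, outdir, name, t0, **info)

        return done

    # -- cohort ------------------------------------------------------------
    done = stage("cohort")
    try:
        if config.cohort_csv is not None:
            cohort = read_cohort_csv(config.cohort_csv)
        else:
            spec = config.cohort_spec or default_spec(seed=config.seed)
            spec = spec.with_(seed=config.seed) if config.cohort_spec is None else spec
            cohort = generate_cohort(spec)
            write_cohort_csv(cohort, outdir / "cohort.csv", include_latent=True)
    except Exception as exc:
        raise PipelineError("cohort", exc)
    done(n_total=cohort.n, n_labeled=len(cohort.labeled), n_censored=len(cohort.censored))

    # -- summary table -----------------------------------------------------
    done = stage("summary")
    try:
        rows = cohort_stats.summarize_cohort(cohort)
        cohort_stats.write_summary_csv(rows, outdir / "cohort_summary.csv")
    except Exception as exc:
        raise PipelineError("summary", exc)
    done(n_variables=len(rows))

    # -- encode / normalize / split ---------------------------------------
    done = stage("prepare")
    try:
        feats = cohort.data[cohort.feature_names]
        norm, _scaler = normalize_frame(feats)
        labeled_mask = cohort.data["followed"] == 1
        lab = cohort.data[labeled_mask]
        x_lab = norm[labeled_mask.to_numpy()].to_numpy(dtype=float)
        y_lab = lab["outcome"].to_numpy(dtype=int)
        t_lab = lab["time"].to_numpy(dtype=float)
        x_cen = norm[~labeled_mask.to_numpy()].to_numpy(dtype=float)
        split = split_cohort(y_lab, t_lab, config.train_ratio, seed=config.seed)
        split.to_json(outdir / "split.json")
        tr, te = split.train_ids, split.test_ids
    except Exception as exc:
        raise PipelineError("prepare", exc)
    done(n_train=len(tr), n_test=len(te))

    # -- four-step training ------------------------------------------------
    done = stage("train")
    try:
        net_cfg = dataclasses.replace(config.net, input_dim=x_lab.shape[1], seed=config.seed)
        keep = undersample_majority(y_lab[tr], seed=config.seed)
        supervised = train_initial(x_lab[tr][keep], y_lab[tr][keep], net_cfg)
        pseudo = pseudo_label(supervised, x_cen)
        final = train_cost_sensitive(
            x_lab[tr], y_lab[tr], x_cen, pseudo, net_cfg, config.loss
        )
        final.save(outdir / "model.json")
        pd.DataFrame(final.history).to_csv(outdir / "training_history.csv", index=False)
    except Exception as exc:
        raise PipelineError("train", exc)
    done(n_pseudo_death=pseudo.n_death, n_pseudo_survival=pseudo.n_survival)

    # -- evaluation --------------------------------------------------------
    done = stage("evaluate")
    try:
        pred_sup = supervised.predict(x_lab[te])
        pred_fin = final.predict(x_lab[te])
        rep_sup = evaluation.classification_metrics(y_lab[te], pred_sup)
        rep_fin = evaluation.classification_metrics(y_lab[te], pred_fin)
        prob_sup = supervised.predict_proba(x_lab[te])[:, 1]
        prob_fin = final.predict_proba(x_lab[te])[:, 1]
        _, rep_sup.auc = evaluation.roc_auc(y_lab[te], prob_sup)
        roc_points, rep_fin.auc = evaluation.roc_auc(y_lab[te], prob_fin)
        rep_fin.nri, rep_fin.idi = evaluation.reclassification_metrics(
            y_lab[te], prob_sup, prob_fin
        )
        baselines = evaluation.baseline_suite(
            x_lab[tr], y_lab[tr], x_lab[te], y_lab[te], seed=config.seed
        )
        payload = {
            "cssnn": evaluation.report_to_dict(rep_fin),
            "supervised_nn": evaluation.report_to_dict(rep_sup),
        }
        for name, rep in baselines.items():
            payload[name] = (
                evaluation.report_to_dict(rep)
                if isinstance(rep, evaluation.MetricsReport)
                else rep
            )
        (outdir / "metrics.json").write_text(json.dumps(payload, indent=2))
        roc_points.to_csv(outdir / "roc_cssnn.csv", index=False)
    except Exception as exc:
        raise PipelineError("evaluate", exc)
    done(cssnn_accuracy=rep_fin.accuracy)

    # -- root cause --------------------------------------------------------
    done = stage("root_cause")
    try:
        preds = root_cause.repeated_prediction_matrix(
            x_lab[tr],
            y_lab[tr],
            x_cen,
            x_lab[te],
            n_runs=config.wjr_runs,
            net_cfg=net_cfg,
            loss_cfg=config.loss,
            seed=config.seed,
        )
        wjr = root_cause.compute_wjr(y_lab[te], preds)
        part = root_cause.assign_subgroups(wjr)
        test_feats = pd.DataFrame(x_lab[te], columns=cohort.feature_names)
        dtc = root_cause.death_threat_coefficient(
            test_feats, part, flag_threshold=config.dtc_threshold
        )
        dtc.table.to_csv(outdir / "dtc_report.csv", index=False)
        pd.DataFrame(
            {"record": np.arange(len(wjr.wjr)), "wjr": wjr.wjr, "group": part.assignment}
        ).to_csv(outdir / "wjr_subgroups.csv", index=False)
    except Exception as exc:
        raise PipelineError("root_cause", exc)
    done(**part.counts())

    # -- survival factors --------------------------------------------------
    done = stage("survival_factors")
    try:
        lab_feats = pd.DataFrame(x_lab, columns=cohort.feature_names)
        lasso = survival_factors.lasso_select(
            lab_feats, y_lab, lambda_grid=config.lasso_grid, seed=config.seed
        )
        cox = survival_factors.stepwise_cox(lab_feats[lasso.selected], y_lab, t_lab)
        cox.summary.to_csv(outdir / "cox_model.csv")
        # KM curves for the strongest selected binary factors
        km_payload = {}
        for v in cox.variables[:4]:
            vals = lab_feats[v].to_numpy()
            if set(np.unique(vals)) <= {0.0, 1.0}:
                curves = survival_factors.km_estimate(
                    t_lab, y_lab, np.where(vals == 1, f"{v}=1", f"{v}=0")
                )
                km_payload[v] = {g: c.to_frame().to_dict("list") for g, c in curves.items()}
        (outdir / "km_curves.json").write_text(json.dumps(km_payload, indent=2))
    except Exception as exc:
        raise PipelineError("survival_factors", exc)
    done(n_lasso=len(lasso.selected), n_cox=len(cox.variables))

    # -- risk score --------------------------------------------------------
    done = stage("risk_score")
    try:
        keep = undersample_majority(y_lab[tr], seed=config.seed + 1)
        model = risk_score.fit_risk_model(
            pd.DataFrame(x_lab[tr][keep], columns=cohort.feature_names),
            y_lab[tr][keep],
            threshold=config.risk_threshold,
        )
        model.to_json(outdir / "risk_model.json")
        scores = risk_score.risk_score(
            model, pd.DataFrame(x_lab[te], columns=cohort.feature_names)
        )
        report = risk_score.threshold_separation_report(
            scores, y_lab[te], config.risk_threshold
        )
        pd.DataFrame(
            {"record": np.arange(len(scores)), "score": scores, "outcome": y_lab[te]}
        ).to_csv(outdir / "risk_scores.csv", index=False)
        (outdir / "risk_report.json").write_text(json.dumps(report, indent=2))
    except Exception as exc:
        raise PipelineError("risk_score", exc)
    done(
        survivors_above=report["survivors_above_threshold"],
        deaths_below=report["deaths_below_threshold"],
    )

    return outdir
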