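"""Group summary statistics for a labeled cohort.

Reproduces the machinery of a clinical baseline table: counts and
percentages (two decimals, half-up) for binary variables, mean +/- SD for
continuous ones, with Mann-Whitney U tests for continuous and Pearson
chi-square tests (no continuity correction by default) for categorical
group comparisons between survivors and deaths.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_cohort import Cohort

__all__ = ["GroupSummaryRow", "percent", "compare_groups", "summarize_cohort"]


@dataclass
class GroupSummaryRow:
    variable: str
    kind: Literal["binary", "continuous"]
    total_n: int | None = None
    survival_n: int | None = None
    death_n: int | None = None
    total_pct: float | None = None
    survival_pct: float | None = None
    death_pct: float | None = None
    total_mean: float | None = None
    total_sd: float | None = None
    survival_mean: float | None = None
    survival_sd: float | None = None
    death_mean: float | None = None
    death_sd: float | None = None
    p_value: float | None = None


def percent(numerator: int, denominator: int) -> float:
    """``100 * numerator / denominator`` rounded half-up to 2 decimals.

    Half-up (not banker's) rounding matches how clinical tables print
    their n (%) cells, e.g. 1265/1370 -> 92.34.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator > denominator or numerator < 0:
        raise ValueError("numerator must be in [0, denominator]")
    frac = Decimal(100 * numerator) / Decimal(denominator)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def compare_groups(
    values_a: np.ndarray,
    values_b: np.ndarray,
    kind: Literal["continuous", "categorical"],
    continuity_correction: bool = False,
) -> tuple[float, float]:
    """Two-group comparison: (statistic, p_value).

    Continuous: two-sided Mann-Whitney U (normal approximation with tie
    correction for larger samples).  Categorical: Pearson chi-square on the
    2x2 table of (involved, not involved) x (group a, group b); the
    continuity correction is off by default.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if kind == "continuous":
        method = "asymptotic" if (len(a) > 20 or len(b) > 20) else "auto"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    table = np.array(
        [
            [np.sum(a == 1), np.sum(a == 0)],
            [np.sum(b == 1), np.sum(b == 0)],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square table has an empty margin")
    if (table == table[0]).all():
        # identical group compositions: no association by construction
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity_correction)
    return float(chi2), float(p)


def summarize_cohort(
    cohort: Cohort, variables: list[str] | None = None
) -> list[GroupSummaryRow]:
    """One summary row per variable over the labeled records.

    Binary features get n (%) per group plus a chi-square p-value;
    continuous features get mean +/- SD plus a Mann-Whitney p-value.  With
    no death group present the summaries are still emitted but p-values are
    left undefined (None).
    """
    lab = cohort.labeled
    if len(lab) == 0:
        raise ValueError("cohort has no labeled records")
    if variables is None:
        variables = cohort.feature_names
    surv = lab[lab["outcome"] == 0]
    dead = lab[lab["outcome"] == 1]
    rows: list[GroupSummaryRow] = []
    for v in variables:
        x = lab[v].to_numpy(dtype=float)
        is_binary = set(np.unique(x)) <= {0.0, 1.0}
        if is_binary:
            tn, sn, dn = int(x.sum()), int(surv[v].sum()), int(dead[v].sum())
            row = GroupSummaryRow(
                variable=v,
                kind="binary",
                total_n=tn,
                survival_n=sn,
                death_n=dn,
                total_pct=percent(tn, len(lab)),
                survival_pct=percent(sn, len(surv)) if len(surv) else None,
                death_pct=percent(dn, len(dead)) if len(dead) else None,
            )
            if len(surv) and len(dead):
                try:
                    _, row.p_value = compare_groups(
                        surv[v].to_numpy(), dead[v].to_numpy(), "categorical"
                    )
                except ValueError:
                    row.p_value = None
        else:
            row = GroupSummaryRow(
                variable=v,
                kind="continuous",
                total_mean=float(np.mean(x)),
                total_sd=float(np.std(x, ddof=1)),
                survival_mean=float(surv[v].mean()) if len(surv) else None,
                survival_sd=float(surv[v].std(ddof=1)) if len(surv) > 1 else None,
                death_mean=float(dead[v].mean()) if len(dead) else None,
                death_sd=float(dead[v].std(ddof=1)) if len(dead) > 1 else None,
            )
            if len(surv) and len(dead):
                _, row.p_value = compare_groups(
                    surv[v].to_numpy(), dead[v].to_numpy(), "continuous"
                )
        rows.append(row)
    return rows


def _fmt_p(p: float | None) -> str:
    if p is None:
        return "NA"
    return f"{p:.4f}" if p >= 0.00005 else "0.0000"


def summary_to_frame(rows: list[GroupSummaryRow]) -> pd.DataFrame:
    """Tabular form of the summary, one variable per row."""
    recs = []
    for r in rows:
        if r.kind == "binary":
            recs.append(
                {
                    "variable": r.variable,
                    "total": f"{r.total_n}({r.total_pct:.2f})",
                    "survival": f"{r.survival_n}({r.survival_pct:.2f})",
                    "death": f"{r.death_n}({r.death_pct:.2f})",
                    "p_value": _fmt_p(r.p_value),
                }
            )
        else:
            recs.append(
                {
                    "variable": r.variable,
                    "total": f"{r.total_mean:.2f}±{r.total_sd:.2f}",
                    "survival": f"{r.survival_mean:.2f}±{r.survival_sd:.2f}",
                    "death": f"{r.death_mean:.2f}±{r.death_sd:.2f}",
                    "p_value": _fmt_p(r.p_value),
                }
            )
    return pd.DataFrame(recs)


def write_summary_csv(rows: list[GroupSummaryRow], path: str | Path) -> None:
    summary_to_frame(rows).to_csv(path, index=False)
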