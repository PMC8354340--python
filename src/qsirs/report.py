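"""Cohort-level accuracy report: all three scores against 30-day death.

One row per score: 2x2 counts, sensitivity/specificity/PPV/NPV (truncated
percents with Clopper-Pearson CIs), odds ratio with Woolf CI, the selected
association test and its p, and the Mann-Whitney AUC of the multi-point
score with its DeLong CI. Pairwise DeLong comparisons of the three AUCs
are returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .accuracy import (
    RocResult,
    association_test,
    delong_compare,
    diagnostic_metrics,
    make_contingency,
    odds_ratio_woolf,
    roc_curve,
)
from .scoring import PatientObservation, score_cohort

__all__ = ["CohortEvaluation", "evaluate_cohort"]

SCORE_NAMES = ("qsofa", "sirs", "qsirs")


@dataclass(frozen=True)
class CohortEvaluation:
    """Full accuracy evaluation of one cohort."""

    scores: pd.DataFrame          # per-patient points/positivity table
    report: pd.DataFrame          # one row per score
    roc: dict[str, RocResult]     # per-score ROC results
    auc_comparisons: pd.DataFrame  # pairwise DeLong z-tests


def evaluate_cohort(observations: list[PatientObservation]) -> CohortEvaluation:
    """Score the cohort and compute the full diagnostic-accuracy report.

    Requires every observation to carry a ``died_30d`` outcome.
    """
    if any(o.died_30d is None for o in observations):
        raise ValueError("outcome column required: every record needs died_30d")
    scored = score_cohort(observations)
    deaths = scored["died_30d"].astype(bool).to_numpy()

    rows = []
    roc: dict[str, RocResult] = {}
    for name in SCORE_NAMES:
        ct = make_contingency(scored[f"{name}_positive"].to_numpy(), deaths)
        metrics = diagnostic_metrics(ct)
        try:
            orr = odds_ratio_woolf(ct)
            or_value, or_lo, or_hi, or_method = (
                orr.odds_ratio, orr.ci_low, orr.ci_high, orr.method,
            )
        except ValueError:
            # zero cell in this cohort: fall back, with the method recorded
            orr = odds_ratio_woolf(ct, haldane=True)
            or_value, or_lo, or_hi, or_method = (
                orr.odds_ratio, orr.ci_low, orr.ci_high, orr.method,
            )
        test = association_test(ct)
        rr = roc_curve(scored[f"{name}_points"].to_numpy(), deaths)
        roc[name] = rr
        rows.append(
            {
                "score": name,
                "tp": ct.tp, "fp": ct.fp, "fn": ct.fn, "tn": ct.tn,
                "sensitivity_pct": metrics.sensitivity.percent(),
                "specificity_pct": metrics.specificity.percent(),
                "ppv_pct": metrics.ppv.percent(),
                "npv_pct": metrics.npv.percent(),
                "odds_ratio": or_value,
                "or_ci_low": or_lo,
                "or_ci_high": or_hi,
                "or_method": or_method,
                "test": test.method,
                "p_value": test.p_value,
                "auc": rr.auc,
                "auc_ci_low": rr.auc_ci[0],
                "auc_ci_high": rr.auc_ci[1],
            }
        )

    comparisons = []
    for i, a in enumerate(SCORE_NAMES):
        for b in SCORE_NAMES[i + 1:]:
            res = delong_compare(
                scored[f"{a}_points"].to_numpy(),
                scored[f"{b}_points"].to_numpy(),
                deaths,
            )
            comparisons.append(
                {
                    "score_a": a,
                    "score_b": b,
                    "auc_a": roc[a].auc,
                    "auc_b": roc[b].auc,
                    "z": res.statistic,
                    "p_value": res.p_value,
                }
            )
    return CohortEvaluation(
        scores=scored,
        report=pd.DataFrame(rows),
        roc=roc,
        auc_comparisons=pd.DataFrame(comparisons),
    )


def plot_roc(evaluation: CohortEvaluation, path: str) -> None:
    """Write a ROC plot (one curve per score) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, rr in evaluation.roc.items():
        fpr = [p[2] for p in rr.operating_points]
        tpr = [p[1] for p in rr.operating_points]
        ax.plot(fpr, tpr, marker="o", label=f"{name.upper()} (AUC={rr.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
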