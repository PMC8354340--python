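"""Diagnostic-accuracy statistics for score-vs-death 2x2 tables and ROC analysis.

The statistical surface mirrors a classical diagnostic-accuracy study:

* 2x2 contingency tables of score positivity against 30-day death;
* sensitivity, specificity, PPV and NPV with exact (Clopper-Pearson)
  binomial confidence intervals;
* odds ratios with Woolf (log-normal) confidence intervals;
* Pearson chi-square (no continuity correction) or Fisher's exact test,
  selected by Cochran's rule (any expected cell < 5 -> Fisher);
* ROC curves with the Mann-Whitney AUC estimator (ties counted half) and
  DeLong variance / paired z-test for comparing two correlated AUCs.

Percentages are rendered by truncation (not rounding) to one decimal,
matching the display convention of the tables this package replicates;
internal values keep full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ContingencyTable",
    "ProportionEstimate",
    "AccuracySummary",
    "OddsRatioResult",
    "TestResult",
    "RocResult",
    "make_contingency",
    "diagnostic_metrics",
    "odds_ratio_woolf",
    "pearson_chi2",
    "fisher_exact",
    "choose_test",
    "association_test",
    "roc_curve",
    "delong_compare",
    "truncate_percent",
]

Z_95 = stats.norm.ppf(0.975)  # 1.959963984540054


def truncate_percent(value: float) -> str:
    """Render a proportion as a percent truncated (not rounded) to one decimal.

    ``0.36363 -> "36.3"``, ``0.97183 -> "97.1"``. Truncation is
    presentation-only; callers keep the full-precision value.
    """
    if not 0.0 <= value <= 1.0 + 1e-12:
        raise ValueError(f"proportion out of [0,1]: {value!r}")
    # the 1e-9 guard absorbs float representation error in ratios of
    # small integer counts without ever crossing a genuine decile boundary
    tenths = math.floor(value * 1000.0 + 1e-9)
    return f"{tenths // 10}.{tenths % 10}"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of score positivity vs death.

    ``tp`` score-positive & died, ``fp`` score-positive & survived,
    ``fn`` score-negative & died, ``tn`` score-negative & survived.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def deaths(self) -> int:
        return self.tp + self.fn

    @property
    def survivors(self) -> int:
        return self.fp + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fp

    @property
    def negatives(self) -> int:
        return self.fn + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=float)

    def expected_counts(self) -> np.ndarray:
        """Expected cell counts under independence, from the margins."""
        rows = np.array([self.positives, self.negatives], dtype=float)
        cols = np.array([self.deaths, self.survivors], dtype=float)
        return np.outer(rows, cols) / self.total


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion with an optional exact CI; ``value`` is None when undefined."""

    value: Optional[float]
    ci: Optional[tuple[float, float]] = None
    reason: Optional[str] = None  # set when undefined

    @property
    def defined(self) -> bool:
        return self.value is not None

    def percent(self) -> str:
        """One-decimal truncated percent, or ``"undefined"``."""
        if self.value is None:
            return "undefined"
        return truncate_percent(self.value)


@dataclass(frozen=True)
class AccuracySummary:
    sensitivity: ProportionEstimate
    specificity: ProportionEstimate
    ppv: ProportionEstimate
    npv: ProportionEstimate


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    method: str  # "woolf" or "woolf_haldane"


@dataclass(frozen=True)
class TestResult:
    p_value: float
    method: str  # "pearson_chi2", "fisher_exact", "delong"
    statistic: Optional[float] = None
    expected_min: Optional[float] = None


@dataclass(frozen=True)
class RocResult:
    """ROC operating points (score >= threshold -> positive) plus AUC.

    ``operating_points`` is an ordered list of
    ``(threshold, sensitivity, 1 - specificity)`` anchored at (0, 0) and
    (1, 1) in ROC space. ``variance`` is the DeLong estimate.
    """

    operating_points: list[tuple[float, float, float]]
    auc: float
    auc_ci: tuple[float, float]
    variance: float


def make_contingency(
    positives: Sequence[bool], deaths: Sequence[bool]
) -> ContingencyTable:
    """Cross-tabulate score positivity against death."""
    pos = np.asarray(positives, dtype=bool)
    dead = np.asarray(deaths, dtype=bool)
    if pos.shape != dead.shape:
        raise ValueError(
            f"length mismatch: {pos.shape[0]} positivity flags vs {dead.shape[0]} outcomes"
        )
    if pos.size == 0:
        raise ValueError("empty input")
    return ContingencyTable(
        tp=int(np.sum(pos & dead)),
        fp=int(np.sum(pos & ~dead)),
        fn=int(np.sum(~pos & dead)),
        tn=int(np.sum(~pos & ~dead)),
    )


def _proportion(num: int, den: int, what: str, with_ci: bool) -> ProportionEstimate:
    if den == 0:
        return ProportionEstimate(None, reason=f"{what} undefined: zero denominator")
    value = num / den
    ci = None
    if with_ci:
        low, high = proportion_confint(num, den, alpha=0.05, method="beta")
        ci = (float(low), float(high))
    return ProportionEstimate(value, ci=ci)


def diagnostic_metrics(ct: ContingencyTable, with_ci: bool = True) -> AccuracySummary:
    """Sensitivity, specificity, PPV and NPV with Clopper-Pearson 95% CIs.

    A metric whose denominator is zero is flagged undefined rather than
    reported as 0.
    """
    return AccuracySummary(
        sensitivity=_proportion(ct.tp, ct.deaths, "sensitivity", with_ci),
        specificity=_proportion(ct.tn, ct.survivors, "specificity", with_ci),
        ppv=_proportion(ct.tp, ct.positives, "PPV", with_ci),
        npv=_proportion(ct.tn, ct.negatives, "NPV", with_ci),
    )


def odds_ratio_woolf(ct: ContingencyTable, haldane: bool = False) -> OddsRatioResult:
    """Odds ratio with the Woolf (log-normal) 95% confidence interval.

    OR = (tp*tn)/(fp*fn); CI = exp(ln OR +/- 1.96 * sqrt(sum of reciprocal
    cells)). With a zero cell the OR is undefined; pass ``haldane=True`` to
    opt in to the Haldane-Anscombe 0.5 correction (applied to every cell,
    recorded in ``method``). No correction is ever applied silently.
    """
    cells = [ct.tp, ct.fp, ct.fn, ct.tn]
    if any(c == 0 for c in cells):
        if not haldane:
            raise ValueError(
                "zero cell: odds ratio undefined; pass haldane=True to opt in "
                "to the Haldane-Anscombe 0.5 correction"
            )
        a, b, c, d = (x + 0.5 for x in cells)
        method = "woolf_haldane"
    else:
        a, b, c, d = (float(x) for x in cells)
        method = "woolf"
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioResult(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        method=method,
    )


def pearson_chi2(ct: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence (1 df, no Yates correction)."""
    expected = ct.expected_counts()
    if np.any(expected == 0):
        raise ValueError("zero margin: chi-square test undefined")
    statistic, p, _, _ = stats.chi2_contingency(ct.as_array(), correction=False)
    return TestResult(
        p_value=float(p),
        method="pearson_chi2",
        statistic=float(statistic),
        expected_min=float(expected.min()),
    )


def fisher_exact(ct: ContingencyTable) -> TestResult:
    """Fisher's exact test, standard two-sided p (sum of hypergeometric
    probabilities of tables, with the observed margins, no more probable
    than the observed one)."""
    _, p = stats.fisher_exact(ct.as_array(), alternative="two-sided")
    return TestResult(
        p_value=float(p),
        method="fisher_exact",
        expected_min=float(ct.expected_counts().min()),
    )


def choose_test(ct: ContingencyTable, min_expected: float = 5.0) -> str:
    """Cochran's rule: Fisher's exact test when any expected cell is below
    ``min_expected`` (default 5), else Pearson chi-square."""
    if float(ct.expected_counts().min()) < min_expected:
        return "fisher_exact"
    return "pearson_chi2"


def association_test(ct: ContingencyTable, min_expected: float = 5.0) -> TestResult:
    """Run the test selected by :func:`choose_test`."""
    if choose_test(ct, min_expected) == "fisher_exact":
        return fisher_exact(ct)
    return pearson_chi2(ct)


# --- ROC / AUC / DeLong ---------------------------------------------------


def _split_by_outcome(
    scores: Sequence[float], deaths: Sequence[bool]
) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    d = np.asarray(deaths, dtype=bool)
    if s.shape != d.shape:
        raise ValueError("scores and outcomes must have equal length")
    if s.size == 0:
        raise ValueError("empty input")
    cases, controls = s[d], s[~d]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("need at least one death and one survivor")
    return cases, controls


def _placements(cases: np.ndarray, controls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midrank placement values (Sun-Xu computation of DeLong's components).

    ``v10[i]`` = fraction of controls scored below case i (ties half);
    ``v01[j]`` = fraction of cases scored above control j (ties half).
    ``v10.mean() == v01.mean()`` is the Mann-Whitney AUC.
    """
    m, n = cases.size, controls.size
    combined = np.concatenate([cases, controls])
    r_all = stats.rankdata(combined)  # midranks
    r_cases = stats.rankdata(cases)
    r_controls = stats.rankdata(controls)
    v10 = (r_all[:m] - r_cases) / n
    v01 = 1.0 - (r_all[m:] - r_controls) / m
    return v10, v01


def mann_whitney_auc(scores: Sequence[float], deaths: Sequence[bool]) -> float:
    """AUC = P(score_death > score_survivor) + 0.5 * P(tie)."""
    cases, controls = _split_by_outcome(scores, deaths)
    v10, _ = _placements(cases, controls)
    return float(v10.mean())


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    s10 = float(np.var(v10, ddof=1)) if v10.size > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if v01.size > 1 else 0.0
    return s10 / v10.size + s01 / v01.size


def roc_curve(scores: Sequence[float], deaths: Sequence[bool]) -> RocResult:
    """ROC curve, Mann-Whitney AUC, and DeLong variance / 95% CI.

    Operating points are generated at every distinct score value
    (classification rule: score >= threshold -> positive) plus the
    all-negative anchor, so the curve runs from (0, 0) to (1, 1).
    """
    cases, controls = _split_by_outcome(scores, deaths)
    s = np.asarray(scores, dtype=float)
    d = np.asarray(deaths, dtype=bool)
    fpr, tpr, thresholds = _sk_roc_curve(d.astype(int), s, drop_intermediate=False)
    points = [(float(t), float(se), float(fp)) for t, se, fp in zip(thresholds, tpr, fpr)]

    v10, v01 = _placements(cases, controls)
    auc = float(v10.mean())
    var = _delong_variance(v10, v01)
    half = Z_95 * math.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return RocResult(operating_points=points, auc=auc, auc_ci=ci, variance=var)


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    deaths: Sequence[bool],
) -> TestResult:
    """DeLong paired z-test of AUC_a - AUC_b for two scores on the same patients.

    The covariance of the two AUCs is estimated from the paired placement
    values, so the correlation induced by sharing patients is accounted
    for. ``statistic`` is the signed z value (positive when AUC_a > AUC_b);
    the p-value is two-sided.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    d = np.asarray(deaths, dtype=bool)
    if not (a.shape == b.shape == d.shape):
        raise ValueError("both score vectors and the outcome must have equal length")
    cases_a, controls_a = _split_by_outcome(a, d)
    cases_b, controls_b = _split_by_outcome(b, d)
    v10a, v01a = _placements(cases_a, controls_a)
    v10b, v01b = _placements(cases_b, controls_b)
    m, n = v10a.size, v01a.size

    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    if m > 1:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    cov = s10 / m + s01 / n
    contrast = np.array([1.0, -1.0])
    var_diff = float(contrast @ cov @ contrast)
    if var_diff <= 1e-15:
        if np.all(a == a[0]) and np.all(b == b[0]):
            raise ValueError("degenerate DeLong variance: both scores are constant")
        if abs(auc_a - auc_b) < 1e-12:
            # e.g. self-comparison: identical placements, zero difference
            return TestResult(p_value=1.0, method="delong", statistic=0.0)
        raise ValueError(
            "degenerate DeLong variance with a non-zero AUC difference"
        )
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(p_value=float(p), method="delong", statistic=float(z))
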