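"""Clinical criterion evaluation and the qSOFA / SIRS / qSIRS score rules.

The three scores are simple counts of dichotomized bedside findings:

* qSOFA — systolic blood pressure <= 100 mmHg, respiratory rate >= 22/min,
  Glasgow Coma Scale <= 14; positive when >= 2 of 3 items are present.
* SIRS — temperature > 38.3 degC or < 36 degC, heart rate > 90/min,
  respiratory rate > 20/min, WBC > 12,000 or < 4,000 /mm3; positive when
  >= 2 of 4 items are present.
* qSIRS — the union of the qSOFA and SIRS items with the respiratory-rate
  item counted once, at a >= 20/min cutoff (six items total); positive when
  >= 2 items are present.

Because the three scores read the respiratory rate at three different
cutoffs (>= 22, > 20, >= 20), the criterion panel stores three distinct RR
flags; the single underlying rate makes them mutually consistent
(rr_qsofa implies rr_qsirs, and rr_sirs implies rr_qsirs).

Boundary handling follows the inequality directions literally; no rounding
is applied to raw vitals before comparison. Units are mmHg, degC,
beats/min, breaths/min and cells/mm3 so that the numeric thresholds apply
without conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "PatientObservation",
    "CriterionPanel",
    "ScorePanel",
    "ValidationError",
    "CohortValidationError",
    "evaluate_criteria",
    "qsofa",
    "sirs",
    "qsirs",
    "compute_scores",
    "score_cohort",
]

# Dichotomization thresholds, in the units of PatientObservation.
SBP_LOW_MAX = 100.0      # mmHg; sbp <= 100 is abnormal
GCS_LOW_MAX = 14         # gcs <= 14 is abnormal
TEMP_HIGH = 38.3         # degC; temp > 38.3 is abnormal
TEMP_LOW = 36.0          # degC; temp < 36 is abnormal
HR_HIGH = 90.0           # beats/min; hr > 90 is abnormal
WBC_HIGH = 12_000.0      # cells/mm3; wbc > 12000 is abnormal
WBC_LOW = 4_000.0        # cells/mm3; wbc < 4000 is abnormal
RR_QSOFA_MIN = 22.0      # breaths/min; rr >= 22 counts for qSOFA
RR_SIRS_GT = 20.0        # breaths/min; rr > 20 counts for SIRS
RR_QSIRS_MIN = 20.0      # breaths/min; rr >= 20 counts for qSIRS

POSITIVITY_CUTOFF = 2    # every score is positive at >= 2 points

#: vitals that must be present before any score can be computed
REQUIRED_VITALS = ("sbp", "temp", "hr", "rr", "gcs", "wbc")


class ValidationError(ValueError):
    """A single observation failed validation; message names the fields."""


class CohortValidationError(ValueError):
    """A batch failed validation.

    Attributes
    ----------
    failures : list of (patient_id, message)
        One entry per offending record.
    """

    def __init__(self, failures: list[tuple[object, str]]):
        self.failures = failures
        lines = ", ".join(f"{pid}: {msg}" for pid, msg in failures)
        super().__init__(f"{len(failures)} invalid record(s): {lines}")


@dataclass(frozen=True)
class PatientObservation:
    """One patient's admission vitals, labs and 30-day outcome.

    Parameters
    ----------
    patient_id : object
        Opaque identifier.
    age : int
        Age in years; the study population is older than 15.
    sex : str
        ``"male"`` or ``"female"``.
    sbp : float
        Systolic blood pressure, mmHg.
    temp : float
        Body temperature, degC.
    hr : float
        Heart rate, beats/min.
    rr : float
        Respiratory rate, breaths/min.
    gcs : int
        Glasgow Coma Scale, integer in [3, 15].
    wbc : float
        White blood cell count, cells/mm3.
    died_30d : bool, optional
        30-day mortality; ``None`` when the outcome is unknown.
    """

    patient_id: object
    age: Optional[int] = None
    sex: Optional[str] = None
    sbp: Optional[float] = None
    temp: Optional[float] = None
    hr: Optional[float] = None
    rr: Optional[float] = None
    gcs: Optional[int] = None
    wbc: Optional[float] = None
    died_30d: Optional[bool] = None

    def validation_errors(self) -> list[str]:
        """Return a list of human-readable validation problems (empty if valid)."""
        problems: list[str] = []
        for field in REQUIRED_VITALS:
            if getattr(self, field) is None:
                problems.append(f"missing required field '{field}'")
        if self.gcs is not None:
            if int(self.gcs) != self.gcs or not (3 <= self.gcs <= 15):
                problems.append(f"gcs out of range [3,15]: {self.gcs!r}")
        for field in ("sbp", "temp", "hr", "rr"):
            value = getattr(self, field)
            if value is not None and value <= 0:
                problems.append(f"{field} must be strictly positive: {value!r}")
        if self.wbc is not None and self.wbc < 0:
            problems.append(f"wbc must be non-negative: {self.wbc!r}")
        if self.age is not None and self.age < 15:
            problems.append(f"age below study inclusion (>= 15): {self.age!r}")
        if self.sex is not None and self.sex not in ("male", "female"):
            problems.append(f"sex must be 'male' or 'female': {self.sex!r}")
        return problems


@dataclass(frozen=True)
class CriterionPanel:
    """Dichotomized criteria for one observation.

    The three RR flags encode the three cutoffs used by the scores; for any
    single underlying respiratory rate, ``rr_qsofa`` implies ``rr_qsirs``
    and ``rr_sirs`` implies ``rr_qsirs``.
    """

    sbp_low: bool
    gcs_low: bool
    temp_abnormal: bool
    hr_high: bool
    wbc_abnormal: bool
    rr_qsofa: bool
    rr_sirs: bool
    rr_qsirs: bool

    def __post_init__(self) -> None:
        if self.rr_qsofa and not self.rr_qsirs:
            raise ValidationError("inconsistent RR flags: rr_qsofa implies rr_qsirs")
        if self.rr_sirs and not self.rr_qsirs:
            raise ValidationError("inconsistent RR flags: rr_sirs implies rr_qsirs")


@dataclass(frozen=True)
class ScorePanel:
    """The three score values with their positivity flags (cutoff >= 2)."""

    qsofa_points: int
    sirs_points: int
    qsirs_points: int
    qsofa_positive: bool
    sirs_positive: bool
    qsirs_positive: bool


def evaluate_criteria(obs: PatientObservation) -> CriterionPanel:
    """Dichotomize an observation's vitals into the criterion panel.

    Raises :class:`ValidationError` when a required vital is missing or out
    of range; no imputation is ever performed.
    """
    problems = obs.validation_errors()
    if problems:
        raise ValidationError(
            f"patient {obs.patient_id!r}: " + "; ".join(problems)
        )
    return CriterionPanel(
        sbp_low=obs.sbp <= SBP_LOW_MAX,
        gcs_low=obs.gcs <= GCS_LOW_MAX,
        temp_abnormal=(obs.temp > TEMP_HIGH) or (obs.temp < TEMP_LOW),
        hr_high=obs.hr > HR_HIGH,
        wbc_abnormal=(obs.wbc > WBC_HIGH) or (obs.wbc < WBC_LOW),
        rr_qsofa=obs.rr >= RR_QSOFA_MIN,
        rr_sirs=obs.rr > RR_SIRS_GT,
        rr_qsirs=obs.rr >= RR_QSIRS_MIN,
    )


def qsofa(panel: CriterionPanel) -> tuple[int, bool]:
    """qSOFA points (0-3) and positivity (>= 2)."""
    points = int(panel.sbp_low) + int(panel.rr_qsofa) + int(panel.gcs_low)
    return points, points >= POSITIVITY_CUTOFF


def sirs(panel: CriterionPanel) -> tuple[int, bool]:
    """SIRS points (0-4) and positivity (>= 2)."""
    points = (
        int(panel.temp_abnormal)
        + int(panel.hr_high)
        + int(panel.rr_sirs)
        + int(panel.wbc_abnormal)
    )
    return points, points >= POSITIVITY_CUTOFF


def qsirs(panel: CriterionPanel) -> tuple[int, bool]:
    """qSIRS points (0-6) and positivity (>= 2).

    Six distinct items: the respiratory rate is counted once, at the
    >= 20/min cutoff, to avoid double-counting the item shared by qSOFA
    and SIRS.
    """
    points = (
        int(panel.sbp_low)
        + int(panel.gcs_low)
        + int(panel.temp_abnormal)
        + int(panel.hr_high)
        + int(panel.wbc_abnormal)
        + int(panel.rr_qsirs)
    )
    return points, points >= POSITIVITY_CUTOFF


def compute_scores(panel: CriterionPanel) -> ScorePanel:
    """All three scores for one criterion panel."""
    qp, qpos = qsofa(panel)
    sp, spos = sirs(panel)
    cp, cpos = qsirs(panel)
    return ScorePanel(
        qsofa_points=qp, sirs_points=sp, qsirs_points=cp,
        qsofa_positive=qpos, sirs_positive=spos, qsirs_positive=cpos,
    )


def score_cohort(observations: Sequence[PatientObservation] | Iterable[PatientObservation]) -> pd.DataFrame:
    """Score every observation; one output row per input row, order preserved.

    The whole batch is validated first: any invalid record fails the batch
    with a :class:`CohortValidationError` listing every offending record
    (records are never silently dropped).

    Returns a DataFrame with columns ``patient_id``, the six ScorePanel
    fields, and ``died_30d``.
    """
    obs_list = list(observations)
    if not obs_list:
        raise ValueError("empty cohort")
    failures: list[tuple[object, str]] = []
    for obs in obs_list:
        problems = obs.validation_errors()
        if problems:
            failures.append((obs.patient_id, "; ".join(problems)))
    if failures:
        raise CohortValidationError(failures)
    rows = []
    for obs in obs_list:
        panel = compute_scores(evaluate_criteria(obs))
        rows.append(
            {
                "patient_id": obs.patient_id,
                "qsofa_points": panel.qsofa_points,
                "qsofa_positive": panel.qsofa_positive,
                "sirs_points": panel.sirs_points,
                "sirs_positive": panel.sirs_positive,
                "qsirs_points": panel.qsirs_points,
                "qsirs_positive": panel.qsirs_positive,
                "died_30d": obs.died_30d,
            }
        )
    return pd.DataFrame(rows)
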