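"""Cohort file schema, reading/writing and validation.

Cohorts are exchanged as UTF-8 comma-separated text with a header row.
Column names carry units so threshold semantics are unambiguous at the
file boundary:

required: ``patient_id, age, sex, sbp_mmHg, temp_C, hr_bpm, rr_bpm, gcs,
wbc_per_mm3``; optional: ``died_30d`` (0/1), ``asa``, ``diagnosis``,
``delay_ge_48h``.

Validation is strict by default: any invalid row fails the read. An
explicit complete-case mode (``drop_invalid=True``) drops and logs bad
rows instead, mirroring the scoring module's missing-data policy.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from .scoring import PatientObservation

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "cohort_frame",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "sbp_mmHg",
    "temp_C",
    "hr_bpm",
    "rr_bpm",
    "gcs",
    "wbc_per_mm3",
)
OPTIONAL_COLUMNS = ("died_30d", "asa", "diagnosis", "delay_ge_48h")

_NUMERIC_COLUMNS = ("age", "sbp_mmHg", "temp_C", "hr_bpm", "rr_bpm", "gcs", "wbc_per_mm3")


class SchemaError(ValueError):
    """The file does not match the documented cohort schema."""


def _normalize_header(df: pd.DataFrame) -> pd.DataFrame:
    """Map case-insensitive header matches onto the documented names."""
    canonical = {c.lower(): c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}
    renames = {}
    for col in df.columns:
        want = canonical.get(str(col).lower())
        if want is not None and want != col:
            renames[col] = want
    if renames:
        logger.info("case-insensitive header match, renaming: %s", renames)
        df = df.rename(columns=renames)
    return df


def read_cohort(path: str | Path, drop_invalid: bool = False) -> list[PatientObservation]:
    """Read and validate a cohort file; records are returned in file order.

    Raises :class:`SchemaError` for missing required columns, and
    ``ValueError`` (naming row number and column) for unparseable or
    out-of-range cells unless ``drop_invalid`` is set, in which case bad
    rows are dropped and logged.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    df = _normalize_header(df)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    observations: list[PatientObservation] = []
    rejected: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # 1-based, counting the header line
        problems: list[str] = []
        values: dict[str, object] = {}
        for col in _NUMERIC_COLUMNS:
            raw = row[col]
            try:
                if pd.isna(raw):
                    problems.append(f"column {col}: missing value")
                    values[col] = None
                else:
                    values[col] = float(raw)
            except (TypeError, ValueError):
                problems.append(f"column {col}: unparseable value {raw!r}")
                values[col] = None

        died = None
        if "died_30d" in df.columns and not pd.isna(row["died_30d"]):
            dv = row["died_30d"]
            if float(dv) in (0.0, 1.0):
                died = bool(int(float(dv)))
            else:
                problems.append(f"column died_30d: must be 0 or 1, got {dv!r}")

        obs = None
        if not problems:
            obs = PatientObservation(
                patient_id=row["patient_id"],
                age=int(values["age"]) if values["age"] is not None else None,
                sex=str(row["sex"]).lower() if not pd.isna(row["sex"]) else None,
                sbp=values["sbp_mmHg"],
                temp=values["temp_C"],
                hr=values["hr_bpm"],
                rr=values["rr_bpm"],
                gcs=int(values["gcs"]) if values["gcs"] == int(values["gcs"]) else values["gcs"],
                wbc=values["wbc_per_mm3"],
                died_30d=died,
            )
            problems = obs.validation_errors()

        if problems:
            msg = f"row {rownum}: " + "; ".join(problems)
            if drop_invalid:
                rejected.append((rownum, msg))
                continue
            raise ValueError(f"{path}: {msg}")
        observations.append(obs)

    logger.info(
        "read %d row(s) from %s: %d accepted, %d rejected",
        len(df), path, len(observations), len(rejected),
    )
    for _, msg in rejected:
        logger.warning("dropped %s", msg)
    return observations


def cohort_frame(observations: Sequence[PatientObservation]) -> pd.DataFrame:
    """Render observations as a DataFrame in the documented column schema."""
    return pd.DataFrame(
        [
            {
                "patient_id": o.patient_id,
                "age": o.age,
                "sex": o.sex,
                "sbp_mmHg": o.sbp,
                "temp_C": o.temp,
                "hr_bpm": o.hr,
                "rr_bpm": o.rr,
                "gcs": o.gcs,
                "wbc_per_mm3": o.wbc,
                "died_30d": None if o.died_30d is None else int(o.died_30d),
            }
            for o in observations
        ]
    )


def write_cohort(observations: Sequence[PatientObservation], path: str | Path) -> None:
    """Write observations to the delimited cohort schema (round-trip safe)."""
    df = cohort_frame(observations)
    if df["died_30d"].isna().all():
        df = df.drop(columns=["died_30d"])
    else:
        df["died_30d"] = df["died_30d"].astype("Int64")
    df.to_csv(path, index=False)
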