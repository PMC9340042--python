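"""Reading and writing the delimited tables the pipeline consumes and emits.

Three input tables (CSV):

* ``patients.csv`` — patient_id, sex, birth_year, diabetes_type, diagnosis_date
* ``screenings.csv`` — patient_id, date, r_right, m_right, r_left, m_left
  (an ungradable eye is coded as empty fields)
* ``visits.csv`` — patient_id, date, hba1c_pct, hba1c_mmol_mol,
  total_cholesterol, hdl, ldl, triglycerides, sbp, dbp, bmi

Dates are ISO-8601.  The cohort is written back as one row per record with
a JSON exclusion-tally sidecar mirroring the cohort flow diagram.
"""

from __future__ import annotations

import hashlib
import json
import math
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .cohort import CohortRecord, PatientRecord, SystemicVisit
from .grading import EyeGrade, ScreeningEpisode

__all__ = [
    "patients_from_frame",
    "episodes_from_frame",
    "visits_from_frame",
    "read_patients",
    "read_screenings",
    "read_visits",
    "cohort_to_frame",
    "write_cohort",
    "write_tally",
    "config_digest",
]

VISIT_FIELDS = (
    "hba1c_pct",
    "hba1c_mmol_mol",
    "total_cholesterol",
    "hdl",
    "ldl",
    "triglycerides",
    "sbp",
    "dbp",
    "bmi",
)


def _opt_float(value) -> Optional[float]:
    if value is None:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(v) else v


def _parse_date(value) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value))


def _eye(r, m) -> Optional[EyeGrade]:
    rv, mv = _opt_float(r), _opt_float(m)
    if rv is None or mv is None:
        return None
    return EyeGrade(int(rv), int(mv))


def patients_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    return [
        PatientRecord(
            patient_id=str(row.patient_id),
            sex=str(row.sex),
            birth_year=int(row.birth_year),
            diabetes_type=str(row.diabetes_type),
            diagnosis_date=_parse_date(row.diagnosis_date),
        )
        for row in df.itertuples(index=False)
    ]


def episodes_from_frame(df: pd.DataFrame) -> list[ScreeningEpisode]:
    return [
        ScreeningEpisode(
            patient_id=str(row.patient_id),
            date=_parse_date(row.date),
            right_eye=_eye(row.r_right, row.m_right),
            left_eye=_eye(row.r_left, row.m_left),
        )
        for row in df.itertuples(index=False)
    ]


def visits_from_frame(df: pd.DataFrame) -> list[SystemicVisit]:
    out = []
    for row in df.itertuples(index=False):
        kwargs = {f: _opt_float(getattr(row, f, None)) for f in VISIT_FIELDS}
        out.append(
            SystemicVisit(patient_id=str(row.patient_id), date=_parse_date(row.date), **kwargs)
        )
    return out


def read_patients(path) -> list[PatientRecord]:
    return patients_from_frame(pd.read_csv(path))


def read_screenings(path) -> list[ScreeningEpisode]:
    return episodes_from_frame(pd.read_csv(path))


def read_visits(path) -> list[SystemicVisit]:
    return visits_from_frame(pd.read_csv(path))


def cohort_to_frame(cohort: Sequence[CohortRecord]) -> pd.DataFrame:
    rows = []
    for r in cohort:
        rows.append(
            {
                "patient_id": r.patient_id,
                "first_date": r.first_date.isoformat(),
                "index_date": r.index_date.isoformat(),
                "risk_group": r.risk_group.value,
                "index_category": r.index_category.value,
                "sex": r.sex,
                "diabetes_type": r.diabetes_type,
                "age_years": r.age_years,
                "duration_years": round(r.duration_years, 4),
                "hba1c_pct": r.hba1c_pct,
                "hba1c_mmol_mol": r.hba1c_mmol_mol,
                "total_cholesterol": r.total_cholesterol,
                "hdl": r.hdl,
                "ldl": r.ldl,
                "triglycerides": r.triglycerides,
                "sbp": r.sbp,
                "dbp": r.dbp,
                "bmi": r.bmi,
                "followup_years": round(r.followup_years, 4),
                "event": r.event,
                "event_or_censor_date": r.event_or_censor_date.isoformat(),
            }
        )
    return pd.DataFrame(rows)


def write_cohort(cohort: Sequence[CohortRecord], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def write_tally(tally: Mapping[str, int], path, meta: Optional[Mapping] = None) -> None:
    doc: dict = {"exclusions": dict(sorted(tally.items()))}
    doc["excluded_total"] = int(sum(tally.values()))
    if meta:
        doc["meta"] = dict(meta)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def config_digest(obj) -> str:
    """Stable SHA-256 digest of a JSON-serialisable configuration mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
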