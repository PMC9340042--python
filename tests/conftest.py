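"""Shared fixtures and episode/record construction helpers."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from retinarisk.cohort import CohortRecord, PatientRecord, SystemicVisit
from retinarisk.grading import BaselineCategory, EyeGrade, RiskGroup, ScreeningEpisode


def grade(code: str | None) -> EyeGrade | None:
    """Parse an eye grade like 'R1M0'; None marks an ungradable eye."""
    if code is None:
        return None
    return EyeGrade(int(code[1]), int(code[3]))


def episode(
    pid: str, when: date, right: str | None, left: str | None
) -> ScreeningEpisode:
    return ScreeningEpisode(pid, when, grade(right), grade(left))


def annual(pid: str, start: date, *grades: tuple[str | None, str | None]):
    """Annual screening stream from ``start`` with per-episode (right, left) codes."""
    return [
        episode(pid, start + timedelta(days=365 * i), r, l)
        for i, (r, l) in enumerate(grades)
    ]


@pytest.fixture
def make_record():
    """Factory for a CohortRecord with sensible defaults, override by keyword."""

    def _make(**kw) -> CohortRecord:
        base = dict(
            patient_id="p1",
            first_date=date(2005, 1, 1),
            index_date=date(2006, 1, 1),
            risk_group=RiskGroup.A,
            index_category=BaselineCategory.NO_DR,
            sex="M",
            diabetes_type="T2",
            age_years=64.0,
            duration_years=3.0,
            hba1c_pct=6.8,
            hba1c_mmol_mol=50.8,
            total_cholesterol=5.0,
            hdl=1.2,
            ldl=2.4,
            triglycerides=3.2,
            sbp=136.0,
            dbp=78.0,
            bmi=31.1,
            followup_years=3.0,
            event=0,
            event_or_censor_date=date(2009, 1, 1),
        )
        base.update(kw)
        return CohortRecord(**base)

    return _make


@pytest.fixture
def make_patient():
    def _make(pid: str, diagnosis: date = date(2003, 1, 1), **kw) -> PatientRecord:
        base = dict(
            patient_id=pid, sex="M", birth_year=1941, diabetes_type="T2", diagnosis_date=diagnosis
        )
        base.update(kw)
        return PatientRecord(**base)

    return _make


@pytest.fixture
def make_visit():
    def _make(pid: str, when: date, **kw) -> SystemicVisit:
        base = dict(
            patient_id=pid,
            date=when,
            hba1c_pct=6.8,
            hba1c_mmol_mol=50.8,
            total_cholesterol=5.0,
            hdl=1.2,
            ldl=2.4,
            triglycerides=3.2,
            sbp=136.0,
            dbp=78.0,
            bmi=31.1,
        )
        base.update(kw)
        return SystemicVisit(**base)

    return _make
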