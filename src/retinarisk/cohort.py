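"""Cohort construction from screening and systemic-visit streams.

A patient enters the analysis cohort when they have at least three retinal
screening episodes (two to define the risk group, at least one more to
observe the outcome), their first two screenings classify into an eligible
risk group (A, D–I), and a complete systemic-visit record exists within a
window before the index (= second) screening.  Follow-up runs from the
index screening to the first later screening showing referable DR
(event = 1) or to the last recorded screening (censored).

Years are computed as days / 365.25 throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from statistics import median
from typing import Iterable, Mapping, Optional, Sequence

from .grading import (
    ELIGIBLE_GROUPS,
    BaselineCategory,
    RiskGroup,
    ScreeningEpisode,
    UngradableEpisodeError,
    baseline_category,
    classify_risk_group,
    is_rdr,
)

__all__ = [
    "SystemicVisit",
    "PatientRecord",
    "CohortRecord",
    "RejectionReason",
    "Rejection",
    "DEFAULT_REQUIRED_COVARIATES",
    "DAYS_PER_YEAR",
    "hba1c_pct_to_mmol_mol",
    "select_index",
    "link_systemic",
    "build_cohort",
    "followup_summary",
]

DAYS_PER_YEAR = 365.25

#: Minimum complete set of systemic variables required for model scoring.
DEFAULT_REQUIRED_COVARIATES = ("hba1c_pct", "total_cholesterol", "sbp")


def hba1c_pct_to_mmol_mol(pct: float) -> float:
    """Convert HbA1c from NGSP percent to IFCC mmol/mol."""
    return (pct - 2.15) * 10.929


@dataclass(frozen=True)
class SystemicVisit:
    """One dated set of systemic measurements; absent values are ``None``."""

    patient_id: str
    date: date
    hba1c_pct: Optional[float] = None
    hba1c_mmol_mol: Optional[float] = None
    total_cholesterol: Optional[float] = None
    hdl: Optional[float] = None
    ldl: Optional[float] = None
    triglycerides: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    bmi: Optional[float] = None

    def has_complete(self, required: Sequence[str]) -> bool:
        return all(getattr(self, name) is not None for name in required)


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: str
    birth_year: int
    diabetes_type: str
    diagnosis_date: date


class RejectionReason(str, Enum):
    TOO_FEW_SCREENINGS = "TOO_FEW_SCREENINGS"
    INELIGIBLE_GRADES = "INELIGIBLE_GRADES"
    RISK_GROUP_BC = "RISK_GROUP_BC"
    NO_SYSTEMIC_MATCH = "NO_SYSTEMIC_MATCH"


@dataclass(frozen=True)
class Rejection:
    patient_id: str
    reason: RejectionReason


@dataclass
class CohortRecord:
    """One eligible patient after cohort construction."""

    patient_id: str
    first_date: date
    index_date: date
    risk_group: RiskGroup
    index_category: BaselineCategory
    sex: str
    diabetes_type: str
    age_years: float
    duration_years: float
    hba1c_pct: Optional[float]
    hba1c_mmol_mol: Optional[float]
    total_cholesterol: Optional[float]
    hdl: Optional[float]
    ldl: Optional[float]
    triglycerides: Optional[float]
    sbp: Optional[float]
    dbp: Optional[float]
    bmi: Optional[float]
    followup_years: float = 0.0
    event: int = 0
    event_or_censor_date: date = field(default_factory=lambda: date(1900, 1, 1))

    @property
    def covariates(self) -> dict[str, Optional[float]]:
        """Numeric covariates addressable by risk-model terms."""
        return {
            "age_years": self.age_years,
            "duration_years": self.duration_years,
            "hba1c_pct": self.hba1c_pct,
            "hba1c_mmol_mol": self.hba1c_mmol_mol,
            "total_cholesterol": self.total_cholesterol,
            "hdl": self.hdl,
            "ldl": self.ldl,
            "triglycerides": self.triglycerides,
            "sbp": self.sbp,
            "dbp": self.dbp,
            "bmi": self.bmi,
        }


def select_index(
    screenings: Sequence[ScreeningEpisode],
) -> tuple[ScreeningEpisode, ScreeningEpisode] | Rejection:
    """Pick the (first, index) screening pair, or reject the patient.

    The index screening is always the *second recorded* episode; a third
    episode must exist to observe the outcome, so patients with fewer than
    three episodes are rejected.  Later grades play no role in selection.
    """
    if len(screenings) < 3:
        pid = screenings[0].patient_id if screenings else "?"
        return Rejection(pid, RejectionReason.TOO_FEW_SCREENINGS)
    ordered = sorted(screenings, key=lambda e: e.date)
    return ordered[0], ordered[1]


def link_systemic(
    index_date: date,
    visits: Sequence[SystemicVisit],
    window_days: int = 180,
    required: Sequence[str] = DEFAULT_REQUIRED_COVARIATES,
) -> SystemicVisit | Rejection:
    """Most recent complete systemic visit on or before the index screening.

    Candidates must fall within ``window_days`` before the index date and
    carry a complete set of the ``required`` variables; among candidates the
    latest date wins.  Visits after the index never qualify.
    """
    candidates = [
        v
        for v in visits
        if v.date <= index_date
        and (index_date - v.date).days <= window_days
        and v.has_complete(required)
    ]
    if not candidates:
        pid = visits[0].patient_id if visits else "?"
        return Rejection(pid, RejectionReason.NO_SYSTEMIC_MATCH)
    return max(candidates, key=lambda v: v.date)


def _followup(
    index: ScreeningEpisode, later: Sequence[ScreeningEpisode]
) -> tuple[float, int, date]:
    """Follow-up time, event flag and end date from post-index screenings.

    Ungradable episodes are skipped for event detection but the last
    recorded episode — gradable or not — anchors censoring.
    """
    event_date: Optional[date] = None
    for ep in later:
        if ep.is_gradable and is_rdr(ep):
            event_date = ep.date
            break
    if event_date is not None:
        end, event = event_date, 1
    else:
        end, event = later[-1].date, 0
    return (end - index.date).days / DAYS_PER_YEAR, event, end


def build_cohort(
    patients: Iterable[PatientRecord],
    screenings: Iterable[ScreeningEpisode],
    visits: Iterable[SystemicVisit],
    window_days: int = 180,
    required: Sequence[str] = DEFAULT_REQUIRED_COVARIATES,
) -> tuple[list[CohortRecord], Counter]:
    """Build the analysis cohort; returns (records, exclusion tally).

    Inclusion requires, in order: at least three screenings; an eligible
    risk group from the first two (B/C and any R2/R3/maculopathy/ungradable
    combination excluded, tallied separately); and a complete systemic visit
    within the linkage window.  The tally counts one reason per rejected
    patient, mirroring a cohort flow diagram.

    Output order follows sorted patient id, so the result is independent of
    input ordering.
    """
    patient_map: dict[str, PatientRecord] = {}
    for p in patients:
        if p.patient_id in patient_map:
            raise ValueError(f"duplicate patient record for {p.patient_id!r}")
        patient_map[p.patient_id] = p

    scr_map: dict[str, list[ScreeningEpisode]] = {}
    for ep in screenings:
        scr_map.setdefault(ep.patient_id, []).append(ep)
    for pid, eps in scr_map.items():
        if pid not in patient_map:
            raise ValueError(f"screening stream references unknown patient {pid!r}")
        eps.sort(key=lambda e: e.date)
        for a, b in zip(eps, eps[1:]):
            if a.date == b.date:
                raise ValueError(f"duplicate screening date {a.date} for patient {pid!r}")

    visit_map: dict[str, list[SystemicVisit]] = {}
    for v in visits:
        if v.patient_id not in patient_map:
            raise ValueError(f"visit stream references unknown patient {v.patient_id!r}")
        visit_map.setdefault(v.patient_id, []).append(v)
    for vs in visit_map.values():
        vs.sort(key=lambda v: v.date)

    records: list[CohortRecord] = []
    tally: Counter = Counter()

    for pid in sorted(patient_map):
        patient = patient_map[pid]
        eps = scr_map.get(pid, [])
        picked = select_index(eps)
        if isinstance(picked, Rejection):
            tally[RejectionReason.TOO_FEW_SCREENINGS.value] += 1
            continue
        first, index = picked
        try:
            group = classify_risk_group(first, index)
        except UngradableEpisodeError:
            # a fully ungradable defining episode cannot establish both-eye status
            tally[RejectionReason.INELIGIBLE_GRADES.value] += 1
            continue
        if group is RiskGroup.INELIGIBLE:
            tally[RejectionReason.INELIGIBLE_GRADES.value] += 1
            continue
        if group.excluded:
            tally[RejectionReason.RISK_GROUP_BC.value] += 1
            continue
        linked = link_systemic(index.date, visit_map.get(pid, []), window_days, required)
        if isinstance(linked, Rejection):
            tally[RejectionReason.NO_SYSTEMIC_MATCH.value] += 1
            continue

        followup_years, event, end_date = _followup(index, eps[2:])
        duration = max(0.0, (index.date - patient.diagnosis_date).days / DAYS_PER_YEAR)
        hba1c_mmol = linked.hba1c_mmol_mol
        if hba1c_mmol is None and linked.hba1c_pct is not None:
            hba1c_mmol = hba1c_pct_to_mmol_mol(linked.hba1c_pct)
        records.append(
            CohortRecord(
                patient_id=pid,
                first_date=first.date,
                index_date=index.date,
                risk_group=group,
                index_category=baseline_category(index),
                sex=patient.sex,
                diabetes_type=patient.diabetes_type,
                age_years=index.date.year - patient.birth_year,
                duration_years=duration,
                hba1c_pct=linked.hba1c_pct,
                hba1c_mmol_mol=hba1c_mmol,
                total_cholesterol=linked.total_cholesterol,
                hdl=linked.hdl,
                ldl=linked.ldl,
                triglycerides=linked.triglycerides,
                sbp=linked.sbp,
                dbp=linked.dbp,
                bmi=linked.bmi,
                followup_years=followup_years,
                event=event,
                event_or_censor_date=end_date,
            )
        )

    return records, tally


def followup_summary(cohort: Sequence[CohortRecord]) -> Mapping[str, float]:
    """Headline follow-up figures: n, person-years, events, median follow-up."""
    if not cohort:
        raise ValueError("followup_summary requires a nonempty cohort")
    times = [r.followup_years for r in cohort]
    return {
        "n": len(cohort),
        "person_years": float(sum(times)),
        "events": int(sum(r.event for r in cohort)),
        "median_followup": float(median(times)),
    }
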