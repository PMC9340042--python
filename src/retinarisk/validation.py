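"""Discrimination and risk-stratified rate tables for censored screening outcomes.

Discrimination is quantified by the cumulative/dynamic time-dependent ROC
AUC at a fixed horizon: cases are subjects whose event occurred by the
horizon, controls are subjects still event-free at the horizon, and cases
are reweighted by the inverse Kaplan-Meier probability of remaining
uncensored just before their event time (IPCW), which corrects for
right-censoring under independence.  When nothing is censored before the
horizon the estimator reduces exactly to the Mann-Whitney U statistic over
cases versus controls; score ties contribute one half.

Confidence intervals are percentile bootstrap over whole patients.
Rate tables stratify a cohort by score quintile or by risk group and
report events per 1000 person-years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Optional, Sequence, Union

import numpy as np
from lifelines import KaplanMeierFitter

from .cohort import CohortRecord
from .risk_models import RiskScore

__all__ = [
    "FULL_PERIOD",
    "SurvivalSample",
    "ValidationResult",
    "RateRow",
    "RateTable",
    "UndefinedAUCError",
    "BootstrapInstabilityError",
    "tdroc_auc",
    "roc_auc_full",
    "bootstrap_ci",
    "rate_per_1000py",
    "quintile_table",
    "group_table",
]

#: Sentinel horizon meaning "the whole follow-up period" (standard ROC).
FULL_PERIOD = "FULL_PERIOD"


class UndefinedAUCError(ValueError):
    """No cases or no controls at the requested horizon."""


class BootstrapInstabilityError(RuntimeError):
    """The statistic was undefined on more than half of the resamples."""


@dataclass(frozen=True)
class SurvivalSample:
    """One subject: risk score, follow-up time in years, event indicator."""

    score: float
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"follow-up time must be positive, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class ValidationResult:
    model_id: str
    horizon: Union[float, str]
    auc: float
    ci_lower: float
    ci_upper: float
    n_bootstrap: int
    roc_points: tuple[tuple[float, float], ...] = ()

    def as_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "horizon": self.horizon,
            "auc": round(self.auc, 4),
            "ci_lower": round(self.ci_lower, 4),
            "ci_upper": round(self.ci_upper, 4),
            "n_bootstrap": self.n_bootstrap,
        }


@dataclass(frozen=True)
class RateRow:
    label: str
    n: int
    events: int
    person_years: float
    rate_per_1000py: float


@dataclass(frozen=True)
class RateTable:
    rows: tuple[RateRow, ...]

    @property
    def total_n(self) -> int:
        return sum(r.n for r in self.rows)

    @property
    def total_events(self) -> int:
        return sum(r.events for r in self.rows)

    @property
    def total_person_years(self) -> float:
        return float(sum(r.person_years for r in self.rows))


def _as_arrays(samples: Sequence[SurvivalSample]):
    scores = np.array([s.score for s in samples], dtype=float)
    times = np.array([s.time for s in samples], dtype=float)
    events = np.array([s.event for s in samples], dtype=int)
    return scores, times, events


def _weighted_mann_whitney(
    case_scores: np.ndarray,
    case_weights: np.ndarray,
    control_scores: np.ndarray,
) -> float:
    """Weighted probability that a case outscores a control; ties count 1/2.

    O((m+n) log n) via sorted cumulative control weights.
    """
    ctrl_sorted = np.sort(control_scores)
    lo = np.searchsorted(ctrl_sorted, case_scores, side="left").astype(float)
    hi = np.searchsorted(ctrl_sorted, case_scores, side="right").astype(float)
    num = float(np.sum(case_weights * (lo + 0.5 * (hi - lo))))
    den = float(np.sum(case_weights) * len(ctrl_sorted))
    return num / den


def _censoring_survival_before(times: np.ndarray, events: np.ndarray, at: np.ndarray) -> np.ndarray:
    """Kaplan-Meier estimate of the censoring survival G evaluated at t-.

    G is fitted treating censoring (event == 0) as the outcome.  The left
    limit G(t-) is the probability of remaining uncensored just before t,
    the standard IPCW weight denominator for a case observed at t.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=(1 - events))
    just_before = np.nextafter(at, -np.inf)
    g = kmf.survival_function_at_times(just_before).to_numpy(dtype=float)
    # a case at t was at risk at t, so G(t-) > 0 in theory; guard numerically
    return np.maximum(g, 1e-12)


def _roc_points(
    case_scores: np.ndarray,
    case_weights: np.ndarray,
    control_scores: np.ndarray,
) -> tuple[tuple[float, float], ...]:
    thresholds = np.unique(np.concatenate([case_scores, control_scores]))[::-1]
    w_total = case_weights.sum()
    n_ctrl = len(control_scores)
    points = [(0.0, 0.0)]
    for c in thresholds:
        tpr = float(case_weights[case_scores >= c].sum() / w_total)
        fpr = float((control_scores >= c).sum() / n_ctrl)
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return tuple(points)


def _tdroc_point_estimate(samples: Sequence[SurvivalSample], horizon: float) -> float:
    scores, times, events = _as_arrays(samples)
    case_mask = (times <= horizon) & (events == 1)
    ctrl_mask = times > horizon
    if not case_mask.any() or not ctrl_mask.any():
        raise UndefinedAUCError(
            f"AUC undefined at horizon {horizon}: "
            f"{int(case_mask.sum())} cases, {int(ctrl_mask.sum())} controls"
        )
    weights = 1.0 / _censoring_survival_before(times, events, times[case_mask])
    return _weighted_mann_whitney(scores[case_mask], weights, scores[ctrl_mask])


def tdroc_auc(
    samples: Sequence[SurvivalSample],
    horizon: float,
    *,
    model_id: str = "model",
    n_bootstrap: int = 0,
    seed: Optional[int] = None,
    compute_roc: bool = True,
) -> ValidationResult:
    """Cumulative/dynamic time-dependent AUC at ``horizon`` years.

    With ``n_bootstrap >= 2`` a percentile 95% CI is attached by
    resampling whole subjects (the IPCW weights are re-estimated on each
    resample); otherwise the CI degenerates to the point estimate.
    """
    auc = _tdroc_point_estimate(samples, horizon)
    if n_bootstrap >= 2:
        lower, upper = bootstrap_ci(
            samples, lambda s: _tdroc_point_estimate(s, horizon), n_boot=n_bootstrap, seed=seed
        )
    else:
        lower = upper = auc
    roc: tuple[tuple[float, float], ...] = ()
    if compute_roc:
        scores, times, events = _as_arrays(samples)
        case_mask = (times <= horizon) & (events == 1)
        ctrl_mask = times > horizon
        weights = 1.0 / _censoring_survival_before(times, events, times[case_mask])
        roc = _roc_points(scores[case_mask], weights, scores[ctrl_mask])
    return ValidationResult(model_id, horizon, auc, lower, upper, max(n_bootstrap, 0), roc)


def _full_point_estimate(samples: Sequence[SurvivalSample]) -> float:
    scores, _, events = _as_arrays(samples)
    case_mask = events == 1
    if not case_mask.any() or case_mask.all():
        raise UndefinedAUCError("standard AUC requires both events and non-events")
    cases = scores[case_mask]
    return _weighted_mann_whitney(cases, np.ones_like(cases), scores[~case_mask])


def roc_auc_full(
    samples: Sequence[SurvivalSample],
    *,
    model_id: str = "model",
    n_bootstrap: int = 0,
    seed: Optional[int] = None,
    compute_roc: bool = True,
) -> ValidationResult:
    """Standard (time-independent) Mann-Whitney AUC over the whole follow-up.

    The event indicator over the entire observation period is the binary
    label; censoring times are ignored.
    """
    auc = _full_point_estimate(samples)
    if n_bootstrap >= 2:
        lower, upper = bootstrap_ci(samples, _full_point_estimate, n_boot=n_bootstrap, seed=seed)
    else:
        lower = upper = auc
    roc: tuple[tuple[float, float], ...] = ()
    if compute_roc:
        scores, _, events = _as_arrays(samples)
        cases = scores[events == 1]
        roc = _roc_points(cases, np.ones_like(cases), scores[events == 0])
    return ValidationResult(model_id, FULL_PERIOD, auc, lower, upper, max(n_bootstrap, 0), roc)


def bootstrap_ci(
    samples: Sequence,
    statistic: Callable[[Sequence], float],
    n_boot: int = 100,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Percentile 95% bootstrap interval, resampling whole subjects.

    Resamples on which the statistic is undefined (e.g. a resample with no
    cases) are dropped; more than 50% failures raises
    :class:`BootstrapInstabilityError`.
    """
    if n_boot < 2:
        raise ValueError(f"n_boot must be at least 2, got {n_boot}")
    rng = np.random.default_rng(seed)
    n = len(samples)
    values = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resample = [samples[i] for i in idx]
        try:
            values.append(statistic(resample))
        except (UndefinedAUCError, ZeroDivisionError):
            failures += 1
    if failures > n_boot / 2:
        raise BootstrapInstabilityError(
            f"statistic undefined on {failures}/{n_boot} bootstrap resamples"
        )
    lower, upper = np.percentile(values, [2.5, 97.5])
    return float(lower), float(upper)


def rate_per_1000py(events: int, person_years: float) -> float:
    """Incidence rate per 1000 person-years, rounded half-up to 1 decimal."""
    if person_years <= 0:
        raise ValueError(f"person_years must be positive, got {person_years}")
    if events < 0:
        raise ValueError(f"events must be nonnegative, got {events}")
    rate = Decimal(1000 * events) / Decimal(repr(person_years))
    return float(rate.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _rate_row(label: str, records: Sequence[CohortRecord]) -> RateRow:
    events = sum(r.event for r in records)
    py = float(sum(r.followup_years for r in records))
    return RateRow(label, len(records), events, py, rate_per_1000py(events, py))


def quintile_table(
    scores: Sequence[RiskScore],
    cohort: Sequence[CohortRecord],
    n_strata: int = 5,
) -> RateTable:
    """Events and rates by risk-score quintile (stratum 1 = lowest scores).

    Strata are near-equal in size (differing by at most one, larger strata
    first); ties spanning a boundary are broken deterministically by stable
    patient-id order.
    """
    if not cohort:
        raise ValueError("quintile_table requires a nonempty cohort")
    if len(scores) != len(cohort):
        raise ValueError("one score per cohort record is required")
    by_id = {r.patient_id: r for r in cohort}
    if set(s.patient_id for s in scores) != set(by_id):
        raise ValueError("scores and cohort cover different patients")
    ranked = sorted(scores, key=lambda s: (s.score, s.patient_id))
    base, rem = divmod(len(ranked), n_strata)
    sizes = [base + 1] * rem + [base] * (n_strata - rem)
    rows = []
    start = 0
    for i, size in enumerate(sizes, start=1):
        chunk = ranked[start : start + size]
        start += size
        rows.append(_rate_row(str(i), [by_id[s.patient_id] for s in chunk]))
    return RateTable(tuple(rows))


def group_table(cohort: Sequence[CohortRecord]) -> RateTable:
    """Events and rates by two-screening risk group (A, D–I as observed)."""
    order = ["A", "D", "E", "F", "G", "H", "I"]
    rows = []
    for label in order:
        members = [r for r in cohort if r.risk_group.value == label]
        if members:
            rows.append(_rate_row(label, members))
    return RateTable(tuple(rows))
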