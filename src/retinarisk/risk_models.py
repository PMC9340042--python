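"""Survival-based and score-based risk engines with externalised coefficients.

Two families of prognostic model are supported:

* a survival engine in which a linear predictor ``lp = sum(beta_i * x_i)``
  scales a baseline survival curve ``S0(t)`` (proportional hazards,
  ``S(t) = S0(t) ** exp(lp)``) and the one-month conditional risk
  ``100 * (1 - S(t + dt) / S(t))`` at ``t`` years since diabetes diagnosis
  is the individual risk score; and
* linear-predictor score models over the two-screening risk group and/or
  systemic covariates, in three variants (grades only; grades plus HbA1c
  and total cholesterol; a single grading plus HbA1c, cholesterol and
  diabetes duration).

Coefficient sets are configuration, not code: the engines are generic over
any term list, categorical term map and baseline-survival specification
supplied in a YAML/JSON document.  The configs shipped with the package
are illustrative synthetic sets — structurally faithful, numerically
invented — since the source coefficient tables are published elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import yaml

from .cohort import CohortRecord
from .grading import BaselineCategory, RiskGroup

__all__ = [
    "CombineMode",
    "GloucesterVariant",
    "BaselineSurvival",
    "Term",
    "CoefficientSet",
    "RiskScore",
    "MissingCovariateError",
    "InvalidGroupError",
    "ExtrapolationError",
    "DegenerateSurvivalError",
    "ConfigError",
    "linear_predictor",
    "survival_probability",
    "icelandic_risk_score",
    "gloucester_score",
    "load_coefficient_set",
]


class ConfigError(ValueError):
    """Malformed coefficient-set configuration."""


class MissingCovariateError(KeyError):
    def __init__(self, variable: str, patient_id: str = "?"):
        super().__init__(variable)
        self.variable = variable
        self.patient_id = patient_id

    def __str__(self) -> str:
        return f"covariate {self.variable!r} missing for patient {self.patient_id!r}"


class InvalidGroupError(ValueError):
    """Scoring requested for a risk group the model was never fitted for (B/C)."""


class ExtrapolationError(ValueError):
    """Time outside the tabulated baseline-survival range."""


class DegenerateSurvivalError(ZeroDivisionError):
    """Conditional risk undefined because S(t) = 0."""


class CombineMode(str, Enum):
    #: proportional hazards: S(t) = S0(t) ** exp(lp)
    PH_POWER = "PH_POWER"
    #: literal reading "exponentiated and multiplied": S(t) = min(1, S0(t) * exp(lp))
    STATED_MULTIPLICATIVE = "STATED_MULTIPLICATIVE"


class GloucesterVariant(str, Enum):
    TWO_GRADES_ONLY = "TWO_GRADES_ONLY"
    TWO_GRADES_SYSTEMIC = "TWO_GRADES_SYSTEMIC"
    ONE_GRADE_SYSTEMIC = "ONE_GRADE_SYSTEMIC"


@dataclass(frozen=True)
class BaselineSurvival:
    """Baseline survival S0(t): exponential, Weibull or tabulated.

    Tabulated curves are interpolated linearly between knots; evaluation
    beyond the last tabulated time raises :class:`ExtrapolationError`.
    """

    family: str  # "exponential" | "weibull" | "table"
    rate: Optional[float] = None
    shape: Optional[float] = None
    scale: Optional[float] = None
    table: Optional[tuple[tuple[float, float], ...]] = None

    def __post_init__(self) -> None:
        if self.family == "exponential":
            if self.rate is None or self.rate < 0:
                raise ConfigError("exponential baseline requires nonnegative 'rate'")
        elif self.family == "weibull":
            if not (self.shape and self.scale) or self.shape <= 0 or self.scale <= 0:
                raise ConfigError("weibull baseline requires positive 'shape' and 'scale'")
        elif self.family == "table":
            tab = self.table
            if not tab or tab[0][0] != 0.0 or tab[0][1] != 1.0:
                raise ConfigError("tabulated baseline must start at (0, 1)")
            ts = [t for t, _ in tab]
            ss = [s for _, s in tab]
            if sorted(ts) != ts or len(set(ts)) != len(ts):
                raise ConfigError("tabulated baseline times must be strictly increasing")
            if any(b > a for a, b in zip(ss, ss[1:])) or any(not 0 <= s <= 1 for s in ss):
                raise ConfigError("tabulated baseline survival must be nonincreasing in [0, 1]")
        else:
            raise ConfigError(f"unknown baseline family {self.family!r}")

    def __call__(self, t: float) -> float:
        if t < 0:
            raise ValueError(f"time must be nonnegative, got {t}")
        if self.family == "exponential":
            return math.exp(-self.rate * t)
        if self.family == "weibull":
            return math.exp(-((t / self.scale) ** self.shape))
        assert self.table is not None
        ts = [p[0] for p in self.table]
        ss = [p[1] for p in self.table]
        if t > ts[-1]:
            raise ExtrapolationError(
                f"t={t} beyond tabulated baseline range [0, {ts[-1]}]"
            )
        for (t0, s0), (t1, s1) in zip(self.table, self.table[1:]):
            if t <= t1:
                if t1 == t0:
                    return s1
                return s0 + (s1 - s0) * (t - t0) / (t1 - t0)
        return ss[-1]


@dataclass(frozen=True)
class Term:
    """One additive term beta * f(x) of a linear predictor.

    ``transform`` is ``identity`` or ``log``; ``center`` (optional) is
    subtracted after the transform, so a term contributes
    ``beta * (f(x) - center)``.
    """

    variable: str
    beta: float
    transform: str = "identity"
    center: Optional[float] = None

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "log"):
            raise ConfigError(f"unknown transform {self.transform!r} for {self.variable!r}")

    def value(self, record: CohortRecord) -> float:
        cov = record.covariates
        if self.variable not in cov:
            raise MissingCovariateError(self.variable, record.patient_id)
        x = cov[self.variable]
        if x is None or (isinstance(x, float) and math.isnan(x)):
            raise MissingCovariateError(self.variable, record.patient_id)
        fx = math.log(x) if self.transform == "log" else float(x)
        if self.center is not None:
            fx -= self.center
        return self.beta * fx


@dataclass(frozen=True)
class CoefficientSet:
    """A named risk model: terms, categorical terms and baseline survival."""

    model_id: str
    combine_mode: CombineMode = CombineMode.PH_POWER
    baseline: Optional[BaselineSurvival] = None
    terms: tuple[Term, ...] = ()
    group_terms: Mapping[str, float] = field(default_factory=dict)
    grade_terms: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label in self.group_terms:
            try:
                group = RiskGroup(label)
            except ValueError as exc:
                raise ConfigError(f"unknown risk group {label!r}") from exc
            if group.excluded or group is RiskGroup.INELIGIBLE:
                raise ConfigError(f"group term for unscoreable group {label!r}")
        for label in self.grade_terms:
            try:
                cat = BaselineCategory(label)
            except ValueError as exc:
                raise ConfigError(f"unknown grade category {label!r}") from exc
            if cat is BaselineCategory.OTHER:
                raise ConfigError("grade term for OTHER category is not scoreable")


@dataclass(frozen=True)
class RiskScore:
    patient_id: str
    model_id: str
    score: float


def _check_scoreable_group(record: CohortRecord) -> None:
    if record.risk_group.excluded or record.risk_group is RiskGroup.INELIGIBLE:
        raise InvalidGroupError(
            f"patient {record.patient_id!r} is in group {record.risk_group.value}; "
            "risk predictions cannot be made for groups B, C or ineligible patients"
        )


def linear_predictor(record: CohortRecord, coefs: CoefficientSet) -> float:
    """Sum of configured term contributions plus any categorical terms.

    Categorical contributions come from ``group_terms`` (keyed by the
    record's two-screening risk group) and/or ``grade_terms`` (keyed by the
    DR category at the index screening) when present in the config.
    """
    lp = sum(term.value(record) for term in coefs.terms)
    if coefs.group_terms:
        _check_scoreable_group(record)
        label = record.risk_group.value
        if label not in coefs.group_terms:
            raise ConfigError(
                f"coefficient set {coefs.model_id!r} has no term for risk group {label}"
            )
        lp += coefs.group_terms[label]
    if coefs.grade_terms:
        label = record.index_category.value
        if label not in coefs.grade_terms:
            raise ConfigError(
                f"coefficient set {coefs.model_id!r} has no term for grade category {label}"
            )
        lp += coefs.grade_terms[label]
    return float(lp)


def survival_probability(t: float, lp: float, coefs: CoefficientSet) -> float:
    """Individual survival probability at time t for linear predictor lp."""
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    if coefs.baseline is None:
        raise ConfigError(f"coefficient set {coefs.model_id!r} has no baseline survival")
    s0 = coefs.baseline(t)
    if coefs.combine_mode is CombineMode.PH_POWER:
        s = s0 ** math.exp(lp)
    else:
        s = min(1.0, s0 * math.exp(lp))
    return min(1.0, max(0.0, s))


def icelandic_risk_score(
    record: CohortRecord,
    coefs: CoefficientSet,
    t: Optional[float] = None,
    delta_t: float = 1.0 / 12.0,
) -> RiskScore:
    """Conditional one-month risk, scaled by 100, as the individual score.

    ``t`` defaults to the record's diabetes duration at the index screening
    (the survival clock starts at diagnosis).  The score is
    ``100 * (1 - S(t + delta_t) / S(t))``, strictly within (0, 100) for a
    strictly decreasing survival curve; the 100x scaling avoids the
    numerically unstable raw-probability scale.
    """
    if t is None:
        t = record.duration_years
    if t < 0:
        raise ValueError(f"time since diagnosis must be nonnegative, got {t}")
    lp = linear_predictor(record, coefs)
    s_t = survival_probability(t, lp, coefs)
    if s_t <= 0.0:
        raise DegenerateSurvivalError(
            f"S(t)=0 at t={t} for patient {record.patient_id!r}; hazard undefined"
        )
    s_t2 = survival_probability(t + delta_t, lp, coefs)
    return RiskScore(record.patient_id, coefs.model_id, 100.0 * (1.0 - s_t2 / s_t))


def gloucester_score(
    record: CohortRecord,
    variant: Union[GloucesterVariant, str],
    coefs: CoefficientSet,
) -> RiskScore:
    """Score under one of the three screening-programme model variants.

    TWO_GRADES_ONLY is purely categorical — the score is the coefficient of
    the record's risk group, so a cohort takes at most seven distinct
    values.  The other variants are ordinary linear predictors over the
    configured terms (which include the categorical grade/group term).
    """
    variant = GloucesterVariant(variant)
    _check_scoreable_group(record)
    if variant is GloucesterVariant.TWO_GRADES_ONLY:
        if not coefs.group_terms:
            raise ConfigError(
                f"coefficient set {coefs.model_id!r} lacks group_terms required by {variant.value}"
            )
        label = record.risk_group.value
        if label not in coefs.group_terms:
            raise ConfigError(
                f"coefficient set {coefs.model_id!r} has no term for risk group {label}"
            )
        return RiskScore(record.patient_id, coefs.model_id, float(coefs.group_terms[label]))
    if variant is GloucesterVariant.TWO_GRADES_SYSTEMIC and not coefs.group_terms:
        raise ConfigError(
            f"coefficient set {coefs.model_id!r} lacks group_terms required by {variant.value}"
        )
    if variant is GloucesterVariant.ONE_GRADE_SYSTEMIC and not coefs.grade_terms:
        raise ConfigError(
            f"coefficient set {coefs.model_id!r} lacks grade_terms required by {variant.value}"
        )
    return RiskScore(record.patient_id, coefs.model_id, linear_predictor(record, coefs))


def _baseline_from_dict(spec: Mapping) -> BaselineSurvival:
    if not isinstance(spec, Mapping) or "family" not in spec:
        raise ConfigError("baseline must be a mapping with a 'family' key")
    family = spec["family"]
    if family == "table":
        pairs = spec.get("points")
        if not isinstance(pairs, Sequence):
            raise ConfigError("tabulated baseline requires a 'points' list of [t, S] pairs")
        table = tuple((float(t), float(s)) for t, s in pairs)
        return BaselineSurvival(family="table", table=table)
    kwargs = {k: float(spec[k]) for k in ("rate", "shape", "scale") if k in spec}
    return BaselineSurvival(family=family, **kwargs)


def coefficient_set_from_dict(doc: Mapping) -> CoefficientSet:
    """Build and validate a CoefficientSet from a parsed config document."""
    if not isinstance(doc, Mapping):
        raise ConfigError("coefficient config must be a mapping")
    if "model_id" not in doc:
        raise ConfigError("coefficient config requires 'model_id'")
    try:
        mode = CombineMode(doc.get("combine_mode", "PH_POWER"))
    except ValueError as exc:
        raise ConfigError(f"unknown combine_mode {doc.get('combine_mode')!r}") from exc
    baseline = _baseline_from_dict(doc["baseline"]) if "baseline" in doc else None
    terms = []
    for i, t in enumerate(doc.get("terms", []) or []):
        if not isinstance(t, Mapping) or "variable" not in t or "beta" not in t:
            raise ConfigError(f"term #{i} must be a mapping with 'variable' and 'beta'")
        terms.append(
            Term(
                variable=str(t["variable"]),
                beta=float(t["beta"]),
                transform=str(t.get("transform", "identity")),
                center=None if t.get("center") is None else float(t["center"]),
            )
        )
    group_terms = {str(k): float(v) for k, v in (doc.get("group_terms") or {}).items()}
    grade_terms = {str(k): float(v) for k, v in (doc.get("grade_terms") or {}).items()}
    try:
        return CoefficientSet(
            model_id=str(doc["model_id"]),
            combine_mode=mode,
            baseline=baseline,
            terms=tuple(terms),
            group_terms=group_terms,
            grade_terms=grade_terms,
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_coefficient_set(path: Union[str, Path]) -> CoefficientSet:
    """Load a coefficient set from a YAML (or JSON) config file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return coefficient_set_from_dict(doc)
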