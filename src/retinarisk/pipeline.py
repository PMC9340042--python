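"""End-to-end orchestration: cohort -> scores -> discrimination -> rate tables.

A :class:`ModelSpec` pairs a coefficient set with the engine that consumes
it (the survival engine, or one of the three score-model variants).  The
four illustrative synthetic coefficient sets shipped with the package form
the default model suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence, Union

from .cohort import CohortRecord, followup_summary
from .risk_models import (
    CoefficientSet,
    GloucesterVariant,
    RiskScore,
    gloucester_score,
    icelandic_risk_score,
    load_coefficient_set,
)
from .validation import (
    RateTable,
    SurvivalSample,
    ValidationResult,
    group_table,
    quintile_table,
    roc_auc_full,
    tdroc_auc,
)

__all__ = ["ModelSpec", "default_model_suite", "score_cohort", "validate_model", "run_validation"]

#: engine selector: the survival engine, or a score-model variant
ICELANDIC = "ICELANDIC"


@dataclass(frozen=True)
class ModelSpec:
    engine: str  # ICELANDIC or a GloucesterVariant value
    coefs: CoefficientSet

    @property
    def model_id(self) -> str:
        return self.coefs.model_id


def default_model_suite() -> list[ModelSpec]:
    """The four shipped illustrative models: survival engine + three variants."""
    cfg_dir = resources.files("retinarisk") / "configs"
    load = lambda name: load_coefficient_set(str(cfg_dir / name))  # noqa: E731
    return [
        ModelSpec(ICELANDIC, load("icelandic_synthetic.yaml")),
        ModelSpec(
            GloucesterVariant.TWO_GRADES_ONLY.value,
            load("gloucester_two_grades_synthetic.yaml"),
        ),
        ModelSpec(
            GloucesterVariant.TWO_GRADES_SYSTEMIC.value,
            load("gloucester_two_grades_systemic_synthetic.yaml"),
        ),
        ModelSpec(
            GloucesterVariant.ONE_GRADE_SYSTEMIC.value,
            load("gloucester_one_grade_systemic_synthetic.yaml"),
        ),
    ]


def score_cohort(cohort: Sequence[CohortRecord], spec: ModelSpec) -> list[RiskScore]:
    if spec.engine == ICELANDIC:
        return [icelandic_risk_score(r, spec.coefs) for r in cohort]
    variant = GloucesterVariant(spec.engine)
    return [gloucester_score(r, variant, spec.coefs) for r in cohort]


def _samples(cohort: Sequence[CohortRecord], scores: Sequence[RiskScore]) -> list[SurvivalSample]:
    return [
        SurvivalSample(score=s.score, time=r.followup_years, event=r.event)
        for r, s in zip(cohort, scores)
    ]


@dataclass(frozen=True)
class ModelValidation:
    spec: ModelSpec
    tdroc: ValidationResult
    roc_full: ValidationResult
    quintiles: Optional[RateTable]  # None for the purely categorical variant
    groups: Optional[RateTable]


def validate_model(
    cohort: Sequence[CohortRecord],
    spec: ModelSpec,
    horizon: float = 2.0,
    n_bootstrap: int = 100,
    seed: Optional[int] = None,
) -> ModelValidation:
    scores = score_cohort(cohort, spec)
    samples = _samples(cohort, scores)
    td = tdroc_auc(
        samples, horizon, model_id=spec.model_id, n_bootstrap=n_bootstrap, seed=seed
    )
    full = roc_auc_full(samples, model_id=spec.model_id, n_bootstrap=n_bootstrap, seed=seed)
    if spec.engine == GloucesterVariant.TWO_GRADES_ONLY.value:
        return ModelValidation(spec, td, full, None, group_table(cohort))
    return ModelValidation(spec, td, full, quintile_table(scores, cohort), None)


def _table_doc(table: RateTable) -> list[dict]:
    return [
        {
            "stratum": r.label,
            "n": r.n,
            "events": r.events,
            "person_years": round(r.person_years, 1),
            "rate_per_1000py": r.rate_per_1000py,
        }
        for r in table.rows
    ]


def run_validation(
    cohort: Sequence[CohortRecord],
    models: Optional[Sequence[ModelSpec]] = None,
    horizon: float = 2.0,
    n_bootstrap: int = 100,
    seed: Optional[int] = None,
) -> dict:
    """Validate every model on the cohort; returns a JSON-serialisable report."""
    if models is None:
        models = default_model_suite()
    report: dict = {"followup": dict(followup_summary(cohort)), "models": {}}
    for spec in models:
        mv = validate_model(cohort, spec, horizon=horizon, n_bootstrap=n_bootstrap, seed=seed)
        entry: dict = {
            "engine": spec.engine,
            "tdroc": mv.tdroc.as_dict(),
            "roc_full": mv.roc_full.as_dict(),
        }
        if mv.quintiles is not None:
            entry["quintile_table"] = _table_doc(mv.quintiles)
        if mv.groups is not None:
            entry["group_table"] = _table_doc(mv.groups)
        report["models"][spec.model_id] = entry
    return report


def render_report(report: dict) -> str:
    """Aligned plain-text rendering of a validation report."""
    lines = []
    fu = report["followup"]
    lines.append(
        f"Cohort: n={fu['n']}  events={fu['events']}  "
        f"person-years={fu['person_years']:.1f}  median follow-up={fu['median_followup']:.2f} y"
    )
    for model_id, entry in report["models"].items():
        lines.append("")
        lines.append(f"Model: {model_id} ({entry['engine']})")
        td, full = entry["tdroc"], entry["roc_full"]
        lines.append(
            f"  TDROC AUC @ {td['horizon']}y: {td['auc']:.2f} "
            f"(95% CI {td['ci_lower']:.2f} to {td['ci_upper']:.2f})"
        )
        lines.append(
            f"  Full-period AUC:    {full['auc']:.2f} "
            f"(95% CI {full['ci_lower']:.2f} to {full['ci_upper']:.2f})"
        )
        for key, title in (("quintile_table", "score quintile"), ("group_table", "risk group")):
            if key in entry:
                lines.append(f"  {'Stratum (' + title + ')':<24}{'n':>6}{'events':>8}"
                             f"{'rate/1000PY':>13}{'PY':>9}")
                for row in entry[key]:
                    lines.append(
                        f"  {row['stratum']:<24}{row['n']:>6}{row['events']:>8}"
                        f"{row['rate_per_1000py']:>13.1f}{row['person_years']:>9.1f}"
                    )
    return "\n".join(lines) + "\n"
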