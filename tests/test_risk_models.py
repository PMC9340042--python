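"""Risk-score engines: linear predictors, survival combination, score variants."""

from __future__ import annotations

import math

import numpy as np
import pytest

from retinarisk.grading import BaselineCategory, RiskGroup
from retinarisk.risk_models import (
    BaselineSurvival,
    CoefficientSet,
    CombineMode,
    ConfigError,
    DegenerateSurvivalError,
    ExtrapolationError,
    GloucesterVariant,
    InvalidGroupError,
    MissingCovariateError,
    Term,
    coefficient_set_from_dict,
    gloucester_score,
    icelandic_risk_score,
    linear_predictor,
    load_coefficient_set,
    survival_probability,
)


def _coefs(**kw) -> CoefficientSet:
    base = dict(model_id="test", baseline=BaselineSurvival("exponential", rate=0.1))
    base.update(kw)
    return CoefficientSet(**base)


class TestLinearPredictor:
    def test_null_model_scores_zero(self, make_record):
        assert linear_predictor(make_record(), _coefs()) == 0.0
        zero = _coefs(terms=(Term("hba1c_pct", 0.0), Term("sbp", 0.0)))
        assert linear_predictor(make_record(), zero) == 0.0

    def test_single_term_product(self, make_record):
        coefs = _coefs(terms=(Term("hba1c_pct", 0.5),))
        assert linear_predictor(make_record(hba1c_pct=6.8), coefs) == pytest.approx(3.4)

    def test_matches_independent_summation(self, make_record):
        # spreadsheet-style tally over four hand-chosen terms
        record = make_record(hba1c_pct=7.4, total_cholesterol=5.3, sbp=142.0, duration_years=6.0)
        spec = [("hba1c_pct", 0.31, 7.4), ("total_cholesterol", 0.12, 5.3),
                ("sbp", 0.015, 142.0), ("duration_years", 0.045, 6.0)]
        expected = sum(beta * x for _, beta, x in spec)
        coefs = _coefs(terms=tuple(Term(v, b) for v, b, _ in spec))
        assert linear_predictor(record, coefs) == pytest.approx(expected, rel=1e-15)

    def test_missing_covariate_error_names_variable(self, make_record):
        coefs = _coefs(terms=(Term("bmi", 0.1),))
        with pytest.raises(MissingCovariateError) as err:
            linear_predictor(make_record(bmi=None), coefs)
        assert "bmi" in str(err.value)

    def test_categorical_terms_add(self, make_record):
        coefs = _coefs(
            terms=(Term("hba1c_pct", 0.5),),
            group_terms={"A": 0.0, "D": 1.2, "E": 0.9, "F": 0.8, "G": 1.0, "H": 0.7, "I": 1.5},
            grade_terms={"NO_DR": 0.0, "MILD_ONE_EYE": 0.6, "MILD_BOTH_EYES": 1.0},
        )
        rec = make_record(
            risk_group=RiskGroup.D, index_category=BaselineCategory.MILD_ONE_EYE, hba1c_pct=6.8
        )
        assert linear_predictor(rec, coefs) == pytest.approx(3.4 + 1.2 + 0.6)


class TestSurvivalProbability:
    def test_null_predictor_recovers_baseline(self):
        coefs = _coefs(baseline=BaselineSurvival("weibull", shape=1.3, scale=20.0))
        for t in (0.0, 1.0, 5.0, 12.5):
            assert survival_probability(t, 0.0, coefs) == pytest.approx(coefs.baseline(t))

    def test_exponential_closed_form_under_ph(self):
        lam, lp = 0.1, math.log(2.0)
        coefs = _coefs(baseline=BaselineSurvival("exponential", rate=lam))
        assert survival_probability(1.0, lp, coefs) == pytest.approx(math.exp(-0.2), rel=1e-12)

    def test_time_zero_is_one_in_both_modes(self):
        for mode in CombineMode:
            coefs = _coefs(combine_mode=mode)
            assert survival_probability(0.0, 1.7, coefs) == 1.0

    def test_multiplicative_mode_capped_at_one(self):
        coefs = _coefs(combine_mode=CombineMode.STATED_MULTIPLICATIVE)
        # exp(lp) > 1/S0(t): a literal multiplicative reading would exceed 1
        assert survival_probability(1.0, 5.0, coefs) == 1.0
        assert survival_probability(1.0, -1.0, coefs) == pytest.approx(
            math.exp(-0.1) * math.exp(-1.0)
        )

    def test_tabulated_baseline_interpolates_and_bounds(self):
        table = BaselineSurvival("table", table=((0.0, 1.0), (1.0, 0.9), (2.0, 0.7)))
        coefs = _coefs(baseline=table)
        assert survival_probability(0.5, 0.0, coefs) == pytest.approx(0.95)
        with pytest.raises(ExtrapolationError):
            survival_probability(2.5, 0.0, coefs)

    def test_invalid_baseline_specs_rejected(self):
        with pytest.raises(ConfigError):
            BaselineSurvival("table", table=((0.0, 1.0), (1.0, 1.1)))
        with pytest.raises(ConfigError):
            BaselineSurvival("weibull", shape=-1.0, scale=2.0)
        with pytest.raises(ConfigError):
            BaselineSurvival("gamma", rate=0.1)


class TestIcelandicScore:
    def test_closed_form_hazard_for_exponential_baseline(self, make_record):
        for lam in (0.01, 0.05, 0.12, 0.5):
            coefs = _coefs(baseline=BaselineSurvival("exponential", rate=lam))
            score = icelandic_risk_score(make_record(), coefs, delta_t=1 / 12).score
            assert score == pytest.approx(100 * (1 - math.exp(-lam / 12)), rel=1e-10)

    def test_no_hazard_scores_zero(self, make_record):
        coefs = _coefs(baseline=BaselineSurvival("exponential", rate=0.0))
        assert icelandic_risk_score(make_record(), coefs).score == 0.0

    def test_monotone_in_linear_predictor(self, make_record):
        coefs = _coefs(terms=(Term("hba1c_pct", 0.5),))
        low = icelandic_risk_score(make_record(hba1c_pct=6.0), coefs).score
        high = icelandic_risk_score(make_record(hba1c_pct=9.0), coefs).score
        assert low < high

    def test_score_within_open_interval(self, make_record):
        coefs = _coefs(baseline=BaselineSurvival("weibull", shape=1.2, scale=8.0))
        score = icelandic_risk_score(make_record(duration_years=10.0), coefs).score
        assert 0.0 < score < 100.0

    def test_ranking_matches_linear_predictor_ordering(self, make_record):
        # strict monotone transform: cohort ordering by score == ordering by lp
        rng = np.random.default_rng(42)
        coefs = _coefs(
            baseline=BaselineSurvival("weibull", shape=1.1, scale=40.0),
            terms=(Term("hba1c_pct", 0.4), Term("sbp", 0.015)),
        )
        records = [
            make_record(
                patient_id=f"p{i}",
                hba1c_pct=float(rng.uniform(5, 11)),
                sbp=float(rng.uniform(100, 190)),
            )
            for i in range(1000)
        ]
        lps = [linear_predictor(r, coefs) for r in records]
        scores = [icelandic_risk_score(r, coefs, t=3.0).score for r in records]
        assert np.array_equal(np.argsort(lps, kind="stable"), np.argsort(scores, kind="stable"))

    def test_degenerate_survival_raises(self, make_record):
        table = BaselineSurvival("table", table=((0.0, 1.0), (1.0, 0.0), (5.0, 0.0)))
        coefs = _coefs(baseline=table)
        with pytest.raises(DegenerateSurvivalError):
            icelandic_risk_score(make_record(duration_years=2.0), coefs)

    def test_engine_is_pure(self, make_record):
        coefs = _coefs(terms=(Term("hba1c_pct", 0.37),))
        rec = make_record(hba1c_pct=7.77)
        first = icelandic_risk_score(rec, coefs).score
        assert all(icelandic_risk_score(rec, coefs).score == first for _ in range(5))


GROUPS = {"A": 0.0, "D": 1.9, "E": 1.4, "F": 1.2, "G": 1.6, "H": 1.1, "I": 2.0}


class TestGloucesterScore:
    def test_two_grades_only_is_group_determined(self, make_record):
        coefs = CoefficientSet("g", group_terms=GROUPS)
        a = make_record(patient_id="a", risk_group=RiskGroup.E, hba1c_pct=6.0)
        b = make_record(patient_id="b", risk_group=RiskGroup.E, hba1c_pct=10.0)
        sa = gloucester_score(a, GloucesterVariant.TWO_GRADES_ONLY, coefs)
        sb = gloucester_score(b, GloucesterVariant.TWO_GRADES_ONLY, coefs)
        assert sa.score == sb.score == GROUPS["E"]

    def test_at_most_seven_distinct_values(self, make_record):
        coefs = CoefficientSet("g", group_terms=GROUPS)
        records = [
            make_record(patient_id=f"p{i}", risk_group=g)
            for i, g in enumerate(list(RiskGroup)[:1] + [RiskGroup.D, RiskGroup.E] * 20)
        ]
        scores = {
            gloucester_score(r, GloucesterVariant.TWO_GRADES_ONLY, coefs).score for r in records
        }
        assert len(scores) <= 7

    def test_null_cholesterol_term_is_a_no_op(self, make_record):
        with_term = CoefficientSet(
            "g", group_terms=GROUPS, terms=(Term("hba1c_pct", 0.3), Term("total_cholesterol", 0.0))
        )
        without = CoefficientSet("g", group_terms=GROUPS, terms=(Term("hba1c_pct", 0.3),))
        rec = make_record(risk_group=RiskGroup.D)
        v = GloucesterVariant.TWO_GRADES_SYSTEMIC
        assert gloucester_score(rec, v, with_term).score == pytest.approx(
            gloucester_score(rec, v, without).score
        )

    def test_one_grade_variant_matches_independent_summation(self, make_record):
        coefs = CoefficientSet(
            "g",
            grade_terms={"NO_DR": 0.0, "MILD_ONE_EYE": 1.0, "MILD_BOTH_EYES": 1.5},
            terms=(
                Term("hba1c_pct", 0.4),
                Term("total_cholesterol", 0.2),
                Term("duration_years", 0.05),
            ),
        )
        rec = make_record(
            index_category=BaselineCategory.MILD_ONE_EYE,
            hba1c_pct=7.2,
            total_cholesterol=5.6,
            duration_years=4.0,
        )
        expected = 1.0 + 0.4 * 7.2 + 0.2 * 5.6 + 0.05 * 4.0
        score = gloucester_score(rec, GloucesterVariant.ONE_GRADE_SYSTEMIC, coefs)
        assert score.score == pytest.approx(expected, rel=1e-15)

    def test_excluded_group_cannot_be_scored(self, make_record):
        coefs = CoefficientSet("g", group_terms=GROUPS)
        rec = make_record(risk_group=RiskGroup.B)
        for variant in GloucesterVariant:
            with pytest.raises(InvalidGroupError):
                gloucester_score(rec, variant, coefs)

    def test_variant_requirements_enforced(self, make_record):
        no_groups = CoefficientSet("g", terms=(Term("hba1c_pct", 0.3),))
        with pytest.raises(ConfigError):
            gloucester_score(make_record(), GloucesterVariant.TWO_GRADES_ONLY, no_groups)
        with pytest.raises(ConfigError):
            gloucester_score(make_record(), GloucesterVariant.ONE_GRADE_SYSTEMIC, no_groups)


class TestConfigLoading:
    def test_shipped_configs_load(self):
        from retinarisk.pipeline import default_model_suite

        suite = default_model_suite()
        assert len(suite) == 4
        assert all(spec.coefs.model_id.endswith("synthetic") for spec in suite)

    def test_yaml_round_trip(self, tmp_path, make_record):
        doc = """
model_id: demo
combine_mode: PH_POWER
baseline: {family: exponential, rate: 0.05}
terms:
  - {variable: hba1c_pct, beta: 0.5, center: 6.8}
"""
        path = tmp_path / "demo.yaml"
        path.write_text(doc)
        coefs = load_coefficient_set(path)
        assert linear_predictor(make_record(hba1c_pct=7.8), coefs) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "doc",
        [
            {"combine_mode": "PH_POWER"},  # no model_id
            {"model_id": "x", "combine_mode": "BOGUS"},
            {"model_id": "x", "terms": [{"variable": "hba1c_pct"}]},  # no beta
            {"model_id": "x", "group_terms": {"B": 1.0}},  # unscoreable group
            {"model_id": "x", "group_terms": {"Z": 1.0}},  # unknown group
            {"model_id": "x", "baseline": {"family": "table", "points": [[0, 0.9]]}},
        ],
    )
    def test_malformed_configs_rejected(self, doc):
        with pytest.raises(ConfigError):
            coefficient_set_from_dict(doc)
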