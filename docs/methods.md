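# Methods

## Outcome and grading logic

Each retinal screening episode carries per-eye grades: retinopathy
R0 (none), R1 (mild/background non-proliferative), R2 (pre-proliferative),
R3 (proliferative), and a maculopathy flag M0/M1. **Referable DR (RDR)**
is maculopathy (M1, at any R level) or R≥2 in either eye. Two explicit
conventions cover combinations the grading scale leaves unstated:

* R0M1 (maculopathy without retinopathy) is treated as referable and as an
  ineligible baseline category — maculopathy triggers referral regardless
  of R level.
* An ungradable eye is represented as missing, never as R0M0. An episode
  with one gradable eye is usable for RDR detection (the gradable eye
  decides) but cannot establish the both-eye status that risk grouping
  requires, so it is ineligible as a defining episode; a fully ungradable
  episode is skipped for event detection but still anchors censoring when
  it is the last recorded episode.

Risk groups A–I are the 3×3 grid of baseline categories (no DR / mild in
one eye / mild in both eyes) at the first two screenings. Groups B and C —
mild DR at the first screening, none at the second — are excluded from all
scoring: the screening-grades-only model was never fitted for them, and
the package raises rather than silently scoring them.

## Cohort construction

The **index screening** is the second recorded episode; at least three
episodes are required (two to define the risk group, one or more to
observe the outcome). Systemic covariates are taken from the most recent
visit at or before the index date that (a) lies within a 180-day window
and (b) carries a complete set of the required variables (HbA1c, total
cholesterol, systolic BP by default). The window is applied to every
candidate visit, not only the immediately preceding one — the stricter of
the two available readings. Completeness is an inclusion rule; there is no
imputation.

Follow-up runs from the index date to the date of the first post-index
screening satisfying the RDR definition (event = 1) or the last recorded
screening (event = 0). Progression between screenings is unobservable, so
the screening date is the operational event date; this interval-observation
structure is the reason a time-dependent ROC is used downstream. Years are
days/365.25; diabetes duration at index is floored at 0 (newly diagnosed
patients can enter with duration 0). Cohort output is sorted by patient
id, so construction is order-independent and idempotent; every exclusion
is tallied by reason (too few screenings / ineligible grades / groups B–C /
no systemic match), mirroring a recruitment flow diagram.

## Risk engines

All engines are pure functions of a cohort record and a **coefficient
set** — external YAML configuration naming additive terms
(`beta · (f(x) − center)`, `f` identity or log), categorical terms keyed
by risk group or by index-screening grade category, and a baseline
survival `S₀(t)` (exponential, Weibull, or tabulated with linear
interpolation; evaluation beyond a table's range is an explicit error).
The shipped configs are labelled synthetic: the engines and validation
machinery, not specific published coefficient values, are the package's
content.

The survival engine computes `lp = β'x`, then
`S(t) = S₀(t)^exp(lp)` (proportional hazards, the default) and scores the
conditional one-month risk

```
score = 100 · (1 − S(t + Δt) / S(t)),    Δt = 1/12 year
```

with `t` = years since diabetes diagnosis at the index screening. The
100× scale avoids the numerically unstable raw-probability scale; since
the transform is strictly monotone in `lp`, ranking — and therefore AUC —
is unaffected. A `STATED_MULTIPLICATIVE` mode
(`S = min(1, S₀(t)·exp(lp))`) is retained for comparison because the
verbal description of such models ("exponentiated and multiplied by the
baseline survival") reads that way literally, but it can exceed 1 without
the cap and is not the default. "One month" is interpreted as 1/12 year,
consistent with the year-based time axis.

The score-model variants: `TWO_GRADES_ONLY` returns the risk-group
coefficient (at most seven distinct values per cohort);
`TWO_GRADES_SYSTEMIC` adds HbA1c, total cholesterol and (in the shipped
config) diabetes duration; `ONE_GRADE_SYSTEMIC` uses the index-screening
grade category plus HbA1c, cholesterol and duration. The schema permits
including or omitting the duration term in the two-grade systemic variant,
since both readings of that model circulate.

## Discrimination

`tdroc_auc` implements the **cumulative/dynamic** time-dependent AUC at a
horizon τ (default 2 years): cases are subjects with an event by τ,
controls are subjects event-free at τ, and each case observed at time
`Tᵢ` is weighted by `1/G(Tᵢ⁻)`, the inverse Kaplan–Meier estimate (via
lifelines) of remaining uncensored just before `Tᵢ`. The control weight
`1/G(τ)` is constant and cancels. Ties in score contribute ½. With no
censoring before the horizon the estimator reduces *exactly* to the
Mann–Whitney U over cases versus controls; that equivalence, an exhaustive
pairwise oracle, and agreement with an independent IPCW implementation
(scikit-survival's `cumulative_dynamic_auc`, machine precision on censored
data) pin its correctness in the tests. The estimator choice — IPCW
cumulative/dynamic rather than a kernel-smoothed variant — is the
standard assumption-light default for this setting.

`roc_auc_full` is the plain Mann–Whitney AUC with the whole-period event
indicator as label, sharing the weighted comparison code path.
Confidence intervals are **percentile bootstrap** (95%, default 100
resamples matching common practice for this analysis), resampling whole
subjects and re-estimating the censoring distribution on each resample;
resamples where the AUC is undefined are dropped, and >50% failures is an
explicit instability error. Rates are `1000·events/person-years` rounded
half-up to one decimal; quintile tables rank by score with ties broken by
patient id (deterministic), stratum sizes differing by at most one with
larger strata first (939 → 188/188/188/188/187). AUCs are reported to two
decimals and rates to one in the text report.

## Synthetic cohort generator

The generator emulates a structured diabetes-care programme: enrolment
uniform over a 3-year window; screenings annually and systemic visits
every 4 months (both with small date jitter); participation windows
uniform on 2.2–6.6 years plus exponential dropout at 0.05/yr, giving
median follow-up near 3 years from the index. Covariates are truncated
normals — HbA1c 6.8% (SD 1.2), SBP 136 (16.4), DBP 78 (9.6), BMI 31.1
(6.4), HDL 1.2 (0.4), LDL 2.4 (0.8), triglycerides 3.2 (2.0), age 64
(range 30–89) — with diabetes duration exponential (mean 3 y, capped at
45). Total cholesterol is not listed in the emulated cohort table; its
default (5.0, SD 1.0 mmol/L) is set for Friedewald-style consistency with
the HDL/LDL/triglyceride values. Visit-level values add small
within-patient noise, and lipid/BMI fields are missing at 2% per visit,
exercising the completeness rule.

Mild retinopathy is a per-eye two-state Markov chain (R0→R1 at 0.03/yr,
R1→R0 at 0.30/yr, initial per-eye mild probability 0.06) observed at
screening dates; regression makes groups B/C arise naturally. The latent
RDR time is exponential with rate `h₀·exp(Σβ(x−μ))` from the index, the
same proportional-hazards family the survival engine assumes, so
discrimination recovery has a known target. Default effects
(HbA1c 0.6/%, SBP 0.025/mmHg, cholesterol 0.3/mmol·L⁻¹, duration
0.08/yr) give a true-linear-predictor SD near 0.9, hence a theoretical
2-year AUC around Φ(0.9/√2) ≈ 0.74 — the realistic discrimination regime
for such models. The baseline hazard (0.010/yr) was calibrated so an
eligible cohort from a 939-patient generation accrues roughly 4%
referrals: the target marginal rate divided by E[exp(lp)], confirmed by
simulation. The event manifests at the first screening after the latent
time; RDR grades at that screening are drawn as maculopathy (50%),
pre-proliferative (40%) or proliferative (10%) in a random eye.

What the generator does **not** emulate: disease-progression biology
(DMO vs PDR pathways, treatment), grade-driven hazards by default (the
chain and the event process are coupled only through shared baseline
risk factors in the configured betas — so the shipped *grade-based*
score models are expected to discriminate weakly on default synthetic
cohorts), attendance behaviour, and prevalent/incident case mixture
beyond the duration distribution. Passing tests therefore demonstrate
correctness of the pipeline's logic and estimators under known
conditions, not clinical performance of any coefficient set on real data.

## Problem sizes and numerical choices

The discrimination-recovery study uses 50 replicate 939-patient
generations; the bootstrap-coverage study uses 200 replicate 300-patient
cohorts at an elevated baseline hazard (0.08/yr) so every cohort carries
enough 2-year events for the AUC to be defined on resamples, with the
reference ("true") AUC taken as the no-censoring Mann–Whitney value of
the true linear predictor on a single 30,000-patient generation from the
same settings. Case weights guard against `G = 0` with a 1e-12 floor;
quintile and bootstrap randomness is fully seed-driven. Known
limitations: percentile (not BCa) intervals with 100 resamples run
slightly below nominal coverage; the interval-observation of events means
"time to RDR" is really "time to first referable screening"; and the
generator's exponential latent times cannot represent non-monotone
hazards.
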