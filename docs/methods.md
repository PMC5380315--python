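# Methods

This note documents the models, numerical choices, and synthetic-data
assumptions behind `lungrisk`, in the spirit of a statistical package's
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Cohort data model and hygiene rules

A subject carries age, gender, race/ethnicity (6 levels), education
(ordinal 1–6), BMI, COPD, emphysema, personal cancer history, family lung
cancer history, pneumonia history, an asbestos flag, and a smoking history
(status current/former, duration in years, intensity in cigarettes/day,
years since quitting, pack-years). Every field except id and age may be
missing; CSV I/O uses comma separation, UTF-8, a header row, and empty
string = missing, and round-trips the typed representation exactly.

Hygiene rules applied before evaluation: intensity > 100 cigarettes/day is
recoded to 100; BMI outside 14–60 kg/m² to the nearest bound. Both rules
are idempotent and fully logged (id, field, old, new). Reported pack-years
are compared against duration·intensity/20 with a 10% relative tolerance;
disagreement is *flagged*, never reconciled, because self-reported
questionnaire quantities admit no principled reconciliation rule.
Never-smokers parse but are excluded (with a warning) from model
evaluation: the risk models are defined for ever-smokers.

Eligibility (`nlst_eligible`) is the pack-year criterion: ≥30 pack-years
and (current smoker or quit <15 y ago). Boundary semantics are literal
("at least 30" → ≥30; "less than 15" → <15). Missing inputs yield an
*indeterminate* result (None), not False, so that incomplete rows cannot
silently count as ineligible. An optional age window (55–74 or 55–80)
supports the trial-enrollment variants; the default applies no window, the
appropriate choice when the criterion is evaluated inside an
already-enrolled cohort.

## Risk calculators

All calculators implement a shared interface: a vectorized
`risk_vector(frame, horizon)` over a cohort DataFrame and a per-subject
`predict`. Missing covariates raise a named incomplete-covariate error —
imputation is an explicit upstream step, never implicit. Coefficients live
in YAML payloads, one file per model, checksummed at load time and recorded
in every pipeline report.

Model structures:

* **Logistic family (PLCOm2012, simplified PLCOm2012).** Linear predictor
  with centered covariates; smoking intensity enters through the published
  reciprocal transform (cigarettes/day ÷ 10)⁻¹, whose domain excludes
  intensity 0 (a domain error, by design). The full model's coefficients
  are transcribed from the original publication. The simplified variant is
  a *separate payload* restricted to age + smoking terms; its refit
  coefficients are not publicly tabulated, so the payload (labelled
  synthetic) reuses the full model's age/smoking terms with the intercept
  recalibrated by +0.11, the mean contribution of the dropped covariates
  in a PLCO-like population.
* **Odds-ratio family (LLP, simplified LLP).** Covariate odds ratios
  multiply the age–sex baseline absolute 5-y risk on the odds scale;
  reference-level subjects receive the baseline exactly. Family-history
  age-of-onset is fixed to "late" (>60 y) by default — the assumption
  required when cohorts record only a yes/no flag — and asbestos is forced
  absent by default for the same reason (both overridable). Payloads are
  synthetic-labelled: increasing duration-category ORs (1, 2.2, 4.3, 8.9),
  comorbidity ORs near 2, and a smooth synthetic baseline table.
* **Annual-cycle family (Bach, Knoke).** Log-linear annual hazards
  converted by p = 1 − exp(−h) and composed over one-year cycles,
  `risk = Σₖ S_lc(k)·S_death(k)·p_lc(k)`; age always advances, duration
  advances for current smokers, quit-years for former smokers. Fractional
  ages are truncated to completed years (annual-cycle framing; no
  interpolation is invented). Bach includes a competing non-lung-cancer
  death hazard; Knoke (lung cancer death) composes without competing
  mortality. Payloads synthetic-labelled.
* **TSCE family (incidence; two death fits).** See below. Gender enters
  only through the parameter sets; payloads synthetic-labelled.

Fixed-time-frame models return their native-horizon score for either
requested horizon (5 or 6 y) without rescaling: they are used as risk
*scores*, matching how a 5-y model is evaluated against 6-y outcomes.
Iterative models honor the horizon exactly.

### Two-stage clonal expansion engine

The TSCE model: normal cells are initiated at rate ν(t) (Poisson), each
initiated cell divides at α, dies/differentiates at β, transforms at μ; a
detected cancer follows the first malignant cell after a fixed lag
(5–6.5 y in the payloads), implemented as a deterministic shift (risk at
age a reflects transformation by a − lag). Smoking scales ν, the net
expansion α−β, and (optionally) μ by 1 + c·doseᵏ, piecewise-constant over
the exposure schedule [0, start):0, [start, quit): intensity, [quit, ∞):0
inferred from the questionnaire history (start = age − duration −
quit-years; a negative inferred start age is a validation error).

Survival is exact: the per-cell no-malignancy probability f satisfies the
Riccati equation `df/ds = (α+β+μ)f − αf² − β`, f(T)=1, solved in closed
form per segment (the solution moves along the hyperbolic flow between the
quadratic's roots q < 1 < p; the branch with f < q, reached when the future
is more carcinogenic than the current segment's stationary regime, is
handled through |1−w| in the logarithms). The survival integral
∫ν(1−f)ds is accumulated analytically, making the batched evaluation pure
numpy algebra (~10⁶ subjects/second), which is what keeps the cohort-scale
analyses cheap. α=0 degenerates to a linear ODE with its own closed form,
reproducing the no-expansion limit S(t)=exp(−ν[t−(1−e^(−μt))/μ]) exactly.

Three independent routes guard the algebra: an adaptive backward-ODE solver
(LSODA, rtol 1e−10; agreement with the closed form to 1e−8 is asserted in
tests), the analytic α=β=0 limit (1e−6), and a direct Monte Carlo
simulation of the branching process (inhomogeneous-Poisson initiations;
per-clone Gillespie with memoryless restarts at segment boundaries;
Kaplan-Meier-style survival with binomial SEs, bit-reproducible under
seed). The hazard −d ln S/dt is computed by a 5-point central difference on
the analytic log-survival (step 0.01 y, error O(δ⁴), well under 1e−6 for
smooth segments); it is accurate in segment interiors and not intended for
points within two steps of an exposure discontinuity.

One structural property worth knowing: with age and duration held fixed,
*increasing* quit-years slides the whole exposure window earlier in life
and can slightly raise TSCE risk (earlier-initiated clones get more
maturation time under positive background expansion). The regression-style
models are monotone non-increasing in quit-years all-else-fixed; for the
TSCE family the meaningful monotonicity is the physical quitting
counterfactual (start age fixed: quitting earlier lowers risk), and that is
what the tests assert.

## Validation metrics

* Calibration groups: deciles of predicted risk by default (quantile
  edges; reduced with a warning when there are fewer distinct predictions;
  a constant prediction vector yields the single point (p̄, ȳ)).
* Calibration slope: coefficient of logit(p) in a logistic regression of
  the outcome on logit(p). Calibration-in-the-large intercept: intercept of
  the offset fit with the coefficient fixed at 1. The two-parameter fit's
  free intercept is also exposed (it is what recovers a known logit-shift
  distortion jointly with the slope). Perfect separation is flagged rather
  than reported as a finite estimate.
* AUC: midrank concordance (ties ½) with a DeLong structural-components
  95% CI. Sensitivity/specificity: Wilson score intervals. Both CI methods
  are declared package choices.
* Count-matched threshold: the n-th largest prediction when the comparator
  selects n people; ties include all tied subjects and the realized count
  is reported with a warning (coarse, categorical models like the LLP
  structure produce large tie groups by construction).

Under multiple imputation, metrics are computed per completed dataset and
pooled by Rubin's rules — AUC on the logit scale (delta-method variances,
back-transformed CI), calibration slope on the raw scale; net-benefit
differences are averaged across imputations before threshold-range
detection.

## Decision curves

Net benefit (TP − FP·t/(1−t))/n; both the weighting factor t/(1−t) and its
reciprocal, the harm ratio (1−t)/t, are exposed as named functions to
prevent reciprocal confusion. The default threshold grid is 0.1%–20% in
0.1% steps (published threshold tables print to 0.1%), and "positive net
benefit against the comparator" means strictly greater at a grid point;
the range reported is [first, last] such point.

## Chained-equation imputation

Conditional models per variable: logistic (binary), multinomial
(race, education), Bayesian normal regression + predictive-mean matching
with 5 donors (continuous) — PMM keeps draws inside observed, bounded,
skewed supports. Sweeps run in increasing-missingness order; draws respect
the hygiene bounds and the structural zero (quit-years exist only for
former smokers, enforced after every draw; for current smokers the cell is
never blanked or imputed). Classifier fits use a lightly ridged logistic
(C=100) for numerical stability, falling back to a marginal draw with a
warning if a fit fails; a degenerate single-class conditional imputes that
class. Reproducibility: one root generator per config seed, spawned per
imputation.

Donor imputation (a variable never measured in the target cohort) stacks
donor and target with a source indicator, fits that variable's conditional
model on donor rows only — the indicator is excluded from *that* model's
design, where it would be a constant column whose ridge-split intercept
share corrupts extrapolation to target rows — and draws target values
inside the sweeps.

Defaults m=20, 10 iterations (configurable; the pipeline uses m=5 when
imputation is needed but unconfigured, and the test suite uses m=2–5 with
2–5 sweeps to keep runtimes in seconds at n≈10⁴).

## Synthetic cohorts

The generator emulates the *published summaries* of the two trial
populations, not their microdata: truncated-normal age; status-specific
smoking quantities as log-normals matched to published medians/IQRs
(σ = ln(q₃/q₁)/1.349); categorical frequencies for race/education;
comorbidity flags logistic in pack-years with the intercept solved
numerically so the marginal frequency hits the published rate. Dependence
structure is deliberately minimal and declared: duration is tied to age
through a start-age distribution (duration = age − start − quit-years,
which automatically satisfies the schema invariants), intensity is drawn
independently given status, and pneumonia/family history/cancer history
are independent flags. The NLST-like scenario rejection-samples the
eligibility constraint (≥30 pack-years, quit <15 y, ages 55–74) so 100% of
subjects qualify.

Outcomes: risk from a designated generating model (default the logistic
6-y incidence model), optionally distorted as
p′ = expit(a + b·logit p) so calibration recovery has a known truth;
Bernoulli incidence; death as a Bernoulli sub-event of incidence with
case fatality 0.5 by default (published 6-y death counts are roughly half
the incidence counts), so death ⇒ incidence always holds.

Missingness: per-field MCAR; MAR (rates doubled above a named observed
predictor's median, halved below, preserving the marginal); or the
*clustered* trial-like profile. The published per-field missing rates under
independent MCAR give a complete-case fraction of ≈0.91, while the trials
report ≈93% complete information — real item nonresponse concentrates in a
minority of respondents. The clustered mechanism assigns a respondent
frailty: a fraction π of subjects carries all missingness at rate r/π,
keeping every per-field marginal at its published r while raising the
joint complete-case rate; π = 0.11 solves
1 − π(1 − Π(1−rⱼ/π)) = 0.93 analytically for the published rates. The
PLCO-like profile blanks pneumonia entirely (never measured there; the
donor-imputation use case), and the complete-case fraction is defined over
partially observed fields only, matching the handled-by-assumption
convention for such fields.

What passing tests on these cohorts do and do not show: they verify the
pipeline's *machinery* — ranking, calibration recovery, pooling,
net-benefit arithmetic — under a known generating process. They do not
estimate the real models' performance on trial data: the synthetic joint
distribution is an assumption, several payloads are synthetic, and
outcomes are generated from one of the candidate models (which that model
will therefore fit best by construction).

## Pipeline and reporting

`run_pipeline` executes recode → never-smoker exclusion → (impute when
missing cells exist; fields missing for *everyone* are assumed absent,
the no-donor convention) → predictions for all requested models → metrics
per model × outcome → decision curves and count-matched comparison against
the pack-year comparator. Reports are plain JSON with CSV side-tables, a
provenance block (seed, config hash, coefficient checksums), and are
byte-identical under a repeated config+seed.

## Problem sizes

The shipped analyses choose sizes where the targeted tolerances are
statistically meaningful: calibration recovery at n = 50,000 (±0.05 covers
≈2–3 SEs across the distortion grid); the criteria-comparison at
n = 40,000 × 10 seeds (≈650 cases per seed); Monte Carlo oracles at
2,500–4,000 replicates with small rate parameters (per-clone event counts
stay O(10²)); imputation checks at n = 5,000–10,000 with m = 3–5. The full
suite runs in well under five minutes on one core.

## Known limitations

* Binary fixed-horizon outcomes only: no censoring-aware metrics, no
  net-reclassification indices, and no modelling of screening effects
  (lead time, overdiagnosis, CT mortality reduction).
* Synthetic payloads reproduce structure and realistic magnitudes, not the
  published constants, for every model except the full logistic incidence
  model; absolute risks from those calculators should not be quoted as the
  original models' outputs.
* The optimal screening threshold is out of scope: choosing one requires
  long-term benefit/harm modelling, not validation metrics.
* The LLP-structure models ignore smoking intensity and time since
  quitting; on cohorts whose outcomes are generated from the logistic
  incidence model (which uses both), their count-matched sensitivity can
  fall below the pack-year criteria — visible in the shipped comparison —
  whereas models using the full smoking history consistently beat the
  criteria.
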