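# lungrisk

A validation toolkit for lung cancer screening **risk prediction models**:
who should be offered low-dose CT screening — everyone matching a pack-year
rule, or the people an absolute-risk model ranks highest?

Current screening recommendations select current/former smokers with at
least 30 pack-years who, if they quit, quit less than 15 years ago. A body
of work argues that absolute-risk models (using age, detailed smoking
history, and risk factors such as COPD or family history) select screening
candidates more efficiently. Comparing nine such models on the original
trial cohorts requires access-restricted microdata; this package implements
the *entire comparison pipeline* as reusable, tested components, exercised
end to end on synthetic cohorts that emulate the published structure of the
NLST and PLCO trial populations. It is aimed at biostatisticians and
screening-policy modellers who want the machinery — calculators, metrics,
decision curves, imputation — with every step verifiable.

## What is inside

* **Nine absolute-risk calculators** behind one registry
  (`lungrisk.get_model`), covering four published model structures:
  - logistic absolute risk with centered/transformed covariates
    (PLCOm2012 and its simplified variant) — for a subject with linear
    predictor `η = β₀ + Σ βⱼ xⱼ`, 6-y risk `p = 1/(1+e^(−η))`;
  - odds-ratio-times-baseline combination (Liverpool Lung Project family):
    `odds = OR_duration · OR_comorbidity · p₀(age,sex)/(1−p₀)`;
  - iterative one-year composition of a cancer hazard with a competing
    death hazard (Bach, Knoke):
    `risk = Σₖ S_lc(k) S_death(k) p_lc(k)`, covariates advancing per cycle;
  - the two-stage clonal expansion (TSCE) carcinogenesis model: initiation
    at rate ν(t), clonal growth at α−β(t), malignant transformation at μ,
    detection lag — solved exactly per exposure segment via the Riccati
    equation `df/ds = (α+β+μ)f − αf² − β`, with an adaptive-ODE solver and
    a Monte Carlo branching-process simulator as independent cross-checks.
* **Validation metrics**: grouped calibration plots, calibration-in-the-large
  and calibration slope, AUC with DeLong confidence intervals,
  sensitivity/specificity with Wilson intervals, and count-matched
  threshold selection.
* **Decision-curve analysis**: net benefit
  `NB(t) = (TP − FP·t/(1−t))/n`, harm ratios, positive-net-benefit
  threshold ranges against the pack-year criteria, and the per-1,000
  interpretation of net-benefit differences.
* **Multiple imputation by chained equations** with cross-cohort donor
  imputation (for a variable one trial never measured) and Rubin's-rules
  pooling.
* **Synthetic cohort generator** reproducing the published marginal
  distributions, eligibility constraints and missing-data profile of
  NLST-like and PLCO-like populations, with outcomes simulated from a
  designated generating model and optional logit-scale calibration
  distortion.
* A thin CLI (`lungrisk simulate|impute|predict|validate|dca|run`) over the
  library, and narrative scripts in `examples/`.

Coefficient payloads live in versioned, checksummed YAML configs
(`src/lungrisk/config/`). The PLCOm2012 coefficients are transcribed from
the model's original publication; payloads whose published constants are
not freely available carry the published *structure* with synthetic
parameter values of realistic magnitude and are explicitly labelled
`*.synthetic.yaml`. Validation results on synthetic cohorts exercise the
machinery; they are not estimates of the real models' trial performance.

## Worked example

`python examples/02_decision_curve_analysis.py` generates a 20,000-person
PLCO-like ever-smoker cohort, simulates 6-y incidence from the PLCOm2012
model, and compares risk-based eligibility with the pack-year criteria:

```
threshold t = 2.5%  (harm ratio 39: one missed case valued as 39 unnecessary screens)
net benefit, model at t : 0.00533 (TP=202, FP=3721)
net benefit, criteria   : 0.00411 (TP=234, FP=5917)
difference +0.00122  =  +1.2 true positives gained, or +47.4 false positives avoided, per 1,000 assessed

model beats the criteria for thresholds in [0.1%, 20.0%] (harm ratios 4.0-999.0)
```

Reading it: at a 2.5% risk threshold an unnecessary screen costs 1/39 of a
detected cancer. The model strategy screens fewer people (3,923 vs 6,151)
yet keeps nearly all the true positives, so its net benefit is higher; the
difference is worth 1.2 extra detected cancers — or equivalently 47 avoided
unnecessary screens — per 1,000 people assessed. The threshold range where
the model wins spans essentially all plausible benefit-harm valuations.

`examples/01_absolute_risk_profiles.py` shows why thresholds must be
model-specific (the same heavy smoker gets 2%–21% 6-y risk across models);
`03` reproduces the count-matched sensitivity comparison, `04` the
imputation-and-pooling workflow, `05` the TSCE hazard trajectories with
their Monte Carlo cross-check.

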