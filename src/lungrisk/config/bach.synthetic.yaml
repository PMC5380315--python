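# Bach-structure model: 1-year lung cancer incidence hazard and 1-year
# competing (non-lung-cancer) death hazard, composed iteratively over
# one-year cycles in which age, duration (current smokers) and quit-years
# (former smokers) advance. Asbestos is forced absent, the assumption used
# when trial cohorts carry no usable asbestos data.
# SYNTHETIC payload: the published spline coefficients could not be
# transcribed; the log-linear terms below are synthetic values of realistic
# magnitude (annual lung-cancer hazard ~0.4% and competing death hazard
# ~1.2% for a 60-year-old current smoker of 20/day for 40 years).
model_id: bach
name: Bach structure (synthetic payload)
outcome: incidence
horizon: 6
form: annual_cycle
force_asbestos_false: true
lung_cancer_hazard:
  intercept: -5.60  # log annual hazard at the reference profile above
  terms:
    age: {type: linear, coef: 0.062, center: 60.0}
    smoking_duration: {type: linear, coef: 0.052, center: 40.0}
    smoking_intensity: {type: log, coef: 0.85, shift: 1.0, scale: 21.0}
    years_since_quit: {type: capped_linear, coef: -0.068, cap: 20.0}
    gender: {type: category, coefs: {male: 0.0, female: -0.10}}
competing_death_hazard:
  intercept: -4.42
  terms:
    age: {type: linear, coef: 0.085, center: 60.0}
    smoking_intensity: {type: log, coef: 0.25, shift: 1.0, scale: 21.0}
    years_since_quit: {type: capped_linear, coef: -0.020, cap: 20.0}
    gender: {type: category, coefs: {male: 0.0, female: -0.25}}
covariates:
  - age
  - gender
  - smoking_status
  - smoking_duration
  - smoking_intensity
  - years_since_quit
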