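# Knoke-structure model: published log-hazard function of age, smoking
# duration, intensity and time since quitting, evaluated on a yearly grid
# and composed as 1 - prod(1 - p_k) with covariates advanced per cycle.
# Predicts lung cancer DEATH; no competing-mortality adjustment.
# SYNTHETIC payload: coefficients are synthetic values of realistic
# magnitude (strong duration power-law, roughly linear intensity effect,
# declining excess hazard after cessation; annual death hazard ~0.22% for a
# 60-year-old current smoker of 20/day for 40 years).
model_id: knoke
name: Knoke structure (synthetic payload)
outcome: death
horizon: 6
form: annual_cycle
lung_cancer_hazard:
  intercept: -6.10
  terms:
    age: {type: linear, coef: 0.040, center: 60.0}
    smoking_duration: {type: log, coef: 3.5, shift: 1.0, scale: 41.0}
    smoking_intensity: {type: log, coef: 1.0, shift: 1.0, scale: 21.0}
    years_since_quit: {type: capped_linear, coef: -0.060, cap: 25.0}
covariates:
  - age
  - smoking_status
  - smoking_duration
  - smoking_intensity
  - years_since_quit
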