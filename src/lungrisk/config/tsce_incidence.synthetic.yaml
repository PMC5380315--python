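# Two-stage clonal expansion model for lung cancer incidence.
# SYNTHETIC payload: the published gender-specific rate parameters could not
# be transcribed; the rates below are synthetic values tuned once to
# realistic magnitudes (hazard of order 1%/year at age 70 for a long-term
# heavy smoker, well under 0.1%/year for never-smoker-like exposure).
# Smoking scales initiation and net clonal expansion via 1 + c * dose^k.
model_id: tsce_incidence
name: TSCE incidence structure (synthetic payload)
outcome: incidence
horizon: 6
form: tsce
lag: 5.0
parameters:
  male:   {nu: 10.0, alpha: 9.0, beta: 8.97, mu: 1.26e-07}
  female: {nu: 8.5, alpha: 9.0, beta: 8.97, mu: 1.26e-07}
dose_response:
  nu_coef: 0.45
  nu_power: 0.6
  promo_coef: 0.36
  promo_power: 0.45
  mu_coef: 0.0
  mu_power: 1.0
covariates:
  - age
  - gender
  - smoking_status
  - smoking_duration
  - smoking_intensity
  - years_since_quit
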