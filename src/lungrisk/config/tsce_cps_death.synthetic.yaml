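# Two-stage clonal expansion model for lung cancer death (CPS-style fit).
# SYNTHETIC payload; see tsce_incidence.synthetic.yaml. Death rates sit
# below incidence rates (longer lag, lower initiation).
model_id: tsce_cps_death
name: TSCE CPS death structure (synthetic payload)
outcome: death
horizon: 6
form: tsce
lag: 6.5
parameters:
  male:   {nu: 7.0, alpha: 9.0, beta: 8.97, mu: 1.2e-07}
  female: {nu: 6.0, alpha: 9.0, beta: 8.97, mu: 1.2e-07}
dose_response:
  nu_coef: 0.40
  nu_power: 0.6
  promo_coef: 0.34
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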