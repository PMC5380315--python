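# Two-stage clonal expansion model for lung cancer death (cohort-study-style
# fit with a steeper dose response in initiation and a shallower one in
# promotion than the CPS-style payload). SYNTHETIC payload; see
# tsce_incidence.synthetic.yaml.
model_id: tsce_nhs_hpfs_death
name: TSCE NHS/HPFS death structure (synthetic payload)
outcome: death
horizon: 6
form: tsce
lag: 6.0
parameters:
  male:   {nu: 6.0, alpha: 8.0, beta: 7.97, mu: 1.5e-07}
  female: {nu: 5.3, alpha: 8.0, beta: 7.97, mu: 1.5e-07}
dose_response:
  nu_coef: 0.55
  nu_power: 0.65
  promo_coef: 0.30
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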