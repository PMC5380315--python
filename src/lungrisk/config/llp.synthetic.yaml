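# LLP-structure model: 5-year absolute lung cancer risk obtained by
# multiplying covariate odds ratios into an age-sex baseline absolute risk.
# SYNTHETIC payload: the published Liverpool Lung Project odds ratios and
# baseline table could not be transcribed here, so the odds ratios and the
# baseline risks below are synthetic values of realistic magnitude (duration
# ORs increasing across categories, comorbidity ORs near 2, baselines rising
# smoothly with age and higher for men). The combination rule is the
# published one.
model_id: llp
name: Liverpool Lung Project structure (synthetic payload)
outcome: incidence
horizon: 5
form: llp_odds
force_asbestos_false: true
family_history_onset: late
baseline_risk:
  # 5-year absolute risk of lung cancer for the covariate reference group,
  # by sex and 5-year age band (left edges; last band is open-ended).
  age_bands: [40, 45, 50, 55, 60, 65, 70, 75, 80, 85]
  male:   [0.0004, 0.0007, 0.0012, 0.0020, 0.0032, 0.0047, 0.0063, 0.0078, 0.0088, 0.0092]
  female: [0.0003, 0.0005, 0.0009, 0.0014, 0.0022, 0.0033, 0.0044, 0.0055, 0.0062, 0.0064]
odds_ratios:
  smoking_duration:
    # categories: 0 (never), (0, 20], (20, 40], (40, inf) years
    breaks: [0.0, 20.0, 40.0]
    ors: [1.0, 2.2, 4.3, 8.9]
  history_pneumonia: 1.8
  asbestos: 1.9
  personal_history_cancer: 2.0
  family_history_lc_early: 2.0
  family_history_lc_late: 1.2
covariates:
  - age
  - gender
  - smoking_duration
  - personal_history_cancer
  - family_history_lc
  - history_pneumonia
  - asbestos
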