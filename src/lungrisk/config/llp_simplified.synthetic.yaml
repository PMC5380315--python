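# Simplified LLP-structure model: age, gender and smoking duration only.
# SYNTHETIC payload (see llp.synthetic.yaml); a separate payload, not a
# covariate-zeroed full model — the baseline absorbs the dropped risk
# factors' average contribution (slightly higher than the full model's
# reference-group baseline).
model_id: llp_simplified
name: Simplified LLP structure (synthetic payload)
outcome: incidence
horizon: 5
form: llp_odds
force_asbestos_false: true
baseline_risk:
  age_bands: [40, 45, 50, 55, 60, 65, 70, 75, 80, 85]
  male:   [0.00046, 0.0008, 0.00138, 0.0023, 0.00368, 0.0054, 0.00724, 0.00897, 0.01012, 0.01058]
  female: [0.000345, 0.000575, 0.001035, 0.00161, 0.00253, 0.0038, 0.00506, 0.006325, 0.00713, 0.00736]
odds_ratios:
  smoking_duration:
    breaks: [0.0, 20.0, 40.0]
    ors: [1.0, 2.2, 4.3, 8.9]
covariates:
  - age
  - gender
  - smoking_duration
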