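# Simplified PLCOm2012: a separate payload restricted to age and smoking
# variables. SYNTHETIC payload: the refit coefficients of the simplified
# variant are not publicly tabulated, so this payload reuses the full
# model's age/smoking terms with an intercept recalibrated (+0.11) to absorb
# the mean contribution of the dropped sociodemographic/comorbidity terms in
# a PLCO-like ever-smoker population. Structure matches the full model.
model_id: plcom2012_simplified
name: Simplified PLCOm2012 (synthetic payload)
outcome: incidence
horizon: 6
form: logistic
intercept: -4.422506
terms:
  age: {type: linear, coef: 0.0778868, center: 62.0}
  smoking_status:
    type: category
    coefs: {former: 0.0, current: 0.2597431}
  smoking_intensity: {type: power, coef: -1.822606, scale: 10.0, power: -1.0, center: 0.4021541613}
  smoking_duration: {type: linear, coef: 0.0317321, center: 27.6605081}
  years_since_quit: {type: linear, coef: -0.0308572, center: 8.593417626}
covariates:
  - age
  - smoking_status
  - smoking_duration
  - smoking_intensity
  - years_since_quit
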