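# PLCOm2012: logistic model for 6-year lung cancer incidence in ever-smokers.
# Coefficients transcribed from the original publication's coefficient table
# (Tammemagi MC et al., N Engl J Med 2013;368:728-36, model 1 "PLCOm2012").
# Continuous covariates are centered at the published centering constants;
# smoking intensity enters through the published nonlinear transform
# ((cigarettes per day / 10)^-1, centered).
model_id: plcom2012
name: PLCOm2012
outcome: incidence
horizon: 6
form: logistic
intercept: -4.532506
terms:
  age: {type: linear, coef: 0.0778868, center: 62.0}
  race:
    type: category
    coefs:
      white: 0.0
      black: 0.3944778
      hispanic: -0.7434744
      asian: -0.466585
      pacific_islander: 1.027152
      native_american: 0.0
  education: {type: linear, coef: -0.0812744, center: 4.0}
  bmi: {type: linear, coef: -0.0274194, center: 27.0}
  copd: {type: indicator, coef: 0.3553063}
  personal_history_cancer: {type: indicator, coef: 0.4589971}
  family_history_lc: {type: indicator, coef: 0.587185}
  smoking_status:
    type: category
    coefs: {former: 0.0, current: 0.2597431}
  smoking_intensity: {type: power, coef: -1.822606, scale: 10.0, power: -1.0, center: 0.4021541613}
  smoking_duration: {type: linear, coef: 0.0317321, center: 27.6605081}
  years_since_quit: {type: linear, coef: -0.0308572, center: 8.593417626}
covariates:
  - age
  - race
  - education
  - bmi
  - copd
  - personal_history_cancer
  - family_history_lc
  - smoking_status
  - smoking_duration
  - smoking_intensity
  - years_since_quit
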