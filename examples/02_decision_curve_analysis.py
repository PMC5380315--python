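"""Decision-curve analysis of risk-based vs pack-year-based screening
eligibility on a synthetic PLCO-like cohort.

Net benefit at threshold t = (TP - FP * t/(1-t)) / n: true positives gained
per person assessed, after charging each unnecessary screen the threshold
odds. A model is useful at t if its net benefit beats the criteria-based
strategy there.
"""

import numpy as np

from lungrisk import cohort_frame, get_model, synth
from lungrisk.cohort import nlst_eligible
from lungrisk.dca import harm_ratio, interpret_nb_delta, net_benefit, positive_nb_range

subjects = synth.generate_cohort(synth.plco_like(20_000), seed=7)
outcomes = synth.simulate_outcomes(subjects, synth.OutcomeSimSpec(seed=8))
y = np.array([o.lc_incidence for o in outcomes])
flags = np.array([bool(nlst_eligible(s)) for s in subjects])
p = get_model("plcom2012").risk_vector(cohort_frame(subjects), 6.0)

t = 0.025
nb_model = net_benefit(p >= t, y, t, "model")
nb_criteria = net_benefit(flags, y, t, "criteria")
delta = nb_model.net_benefit - nb_criteria.net_benefit
tp_gain, fp_avoided = interpret_nb_delta(delta, t)

print(f"threshold t = {t:.1%}  (harm ratio {harm_ratio(t):.0f}: one missed case "
      f"valued as {harm_ratio(t):.0f} unnecessary screens)")
print(f"net benefit, model at t : {nb_model.net_benefit:.5f} "
      f"(TP={nb_model.tp}, FP={nb_model.fp})")
print(f"net benefit, criteria   : {nb_criteria.net_benefit:.5f} "
      f"(TP={nb_criteria.tp}, FP={nb_criteria.fp})")
print(f"difference {delta:+.5f}  =  {tp_gain:+.1f} true positives gained, or "
      f"{fp_avoided:+.1f} false positives avoided, per 1,000 assessed")

rng = positive_nb_range(p, y, flags)
print(f"\nmodel beats the criteria for thresholds in "
      f"[{rng.lower:.1%}, {rng.upper:.1%}] "
      f"(harm ratios {harm_ratio(rng.upper):.1f}-{harm_ratio(rng.lower):.1f})")
print("Across that whole range of benefit-harm valuations, risk-based "
      "selection is the better strategy.")
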