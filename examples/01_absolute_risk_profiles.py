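"""Absolute 6-year risks for distinct smoking profiles under all nine models.

The same person gets a different absolute risk from every model: the models
were developed in different populations, for different outcomes (incidence
vs death), with different structures. That spread is why each model needs
its own screening-eligibility threshold.
"""

from lungrisk import MODEL_IDS, Subject, SmokingHistory, predict

profiles = [
    Subject(id="heavy-current", age=70, gender="male", race="white", education=2,
            bmi=28, copd=True, emphysema=False, personal_history_cancer=False,
            family_history_lc=True, history_pneumonia=False, asbestos=False,
            smoking=SmokingHistory(status="current", duration=55, intensity=30,
                                   years_since_quit=0)),
    Subject(id="moderate-former", age=63, gender="female", race="black", education=5,
            bmi=25, copd=False, emphysema=False, personal_history_cancer=False,
            family_history_lc=False, history_pneumonia=True, asbestos=False,
            smoking=SmokingHistory(status="former", duration=40, intensity=15,
                                   years_since_quit=10)),
    Subject(id="light-former", age=65, gender="male", race="asian", education=4,
            bmi=24, copd=False, emphysema=False, personal_history_cancer=False,
            family_history_lc=False, history_pneumonia=False, asbestos=False,
            smoking=SmokingHistory(status="former", duration=30, intensity=10,
                                   years_since_quit=14)),
    Subject(id="light-current", age=50, gender="female", race="white", education=5,
            bmi=22, copd=False, emphysema=False, personal_history_cancer=False,
            family_history_lc=False, history_pneumonia=False, asbestos=False,
            smoking=SmokingHistory(status="current", duration=30, intensity=5,
                                   years_since_quit=0)),
]

print(f"{'model':24s}" + "".join(f"{p.id:>18s}" for p in profiles))
for model_id in MODEL_IDS:
    row = [predict(model_id, s, 6).probability for s in profiles]
    print(f"{model_id:24s}" + "".join(f"{100*r:17.2f}%" for r in row))

print("\nEach column is one person; each row a model's 6-y absolute risk "
      "(incidence or death, per the model's target outcome).")
print("Within a column, risks differ by several-fold across models — "
      "thresholds must be model-specific.")
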