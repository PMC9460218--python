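"""Classify glucose-tolerance responders in a synthetic cohort.

A responder must, at the same week (2 or 4), show: glucose iAUC(0-90)
down >= 25%, glucose AUC(0-90) down, and insulin iAUC(0-90) down >= 15%,
comparing the test-food time point with the control time point.
"""

from metabologenome import CohortConfig, generate_cohort
from metabologenome.ogtt import glucose_tolerance_indices
from metabologenome.responder import classify_responders, score_indices

dataset = generate_cohort(CohortConfig(seed=1))
indices = glucose_tolerance_indices(dataset.ogtt_curves)

calls = classify_responders(indices)
responders = calls[calls.responder_overall].subject.unique()
print(f"responders: {sorted(responders)} of {calls.subject.nunique()} subjects")

scores = score_indices(indices)
week4 = scores[(scores.quantity == "glucose_AUC_0_90") & (scores.week == 4)]
print("glucose AUC responder scores (week 4), most improved first:")
print(week4.nsmallest(5, "score")[["subject", "score"]].to_string(index=False))
# negative score = the test food lowered the subject's glucose AUC relative
# to their control period (improvement).
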