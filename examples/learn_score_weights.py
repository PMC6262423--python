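"""Run the greedy integer weight search on a cohort with a known score model.

The cohort's outcome is drawn from a logistic model on the published
weighted score, so the search should escalate the high-severity levels
first. The escalating configuration holds the operating threshold at the
baseline maximum (4), where sensitivity starts at zero and specificity at
one; the default Youden configuration is shown for contrast — it is very
conservative and usually keeps the equal-weight baseline.
"""

from neoscore import SearchConfig, baseline_weights, learn_weights, simulate_from_score_model

cohort = simulate_from_score_model(n=2000, beta=2.0, seed=0)

for label, config in (
    ("youden (default)", SearchConfig()),
    ("fixed threshold 4", SearchConfig(threshold_rule=f"fixed:{baseline_weights().max_score}")),
):
    weights, trace = learn_weights(cohort, config)
    accepted = trace.accepted()
    final = accepted[-1]
    print(f"--- {label}: {len(accepted) - 1} accepted escalations")
    for name, points in weights.as_dict().items():
        print(f"    {name:24s} {points}")
    print(f"    operating point: threshold >{final.threshold}, "
          f"sens {float(final.sensitivity):.2f}, spec {float(final.specificity):.2f}")
print()
print("An escalation is kept only while sensitivity strictly rises and")
print("specificity does not fall; weights therefore rank injury severity.")
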