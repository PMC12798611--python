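"""Baseline comparison of the five GAD treatment strategies.

Simulates 20,000 individuals per arm over two 6-month cycles, then prints
each arm's 12-month totals and digital CBT's net monetary benefit (NMB)
against every alternative.  A positive NMB means digital CBT is
cost-beneficial relative to that comparator: it bundles treatment-cost
differences, disease-cost savings (healthcare plus lost work days) and —
in the societal perspective — QALY gains valued at $50,000 each.
"""

from gadsim import (
    ArmId,
    aggregate_arm,
    default_parameters,
    nmb_matrix,
    perspectives,
    simulate_arm,
)
from gadsim.cea import nmb_table, outcomes_table

params = default_parameters()
outcomes = {
    arm: aggregate_arm(simulate_arm(arm, params, seed=1), params)
    for arm in ArmId
}

print("12-month totals per 20,000-person arm:")
print(outcomes_table(outcomes).to_string(index=False))

results = nmb_matrix(outcomes, ArmId.DIGITAL_CBT, list(perspectives(params)))
print("\nNMB per person, digital CBT vs comparator ($; payer counts dollars")
print("only, societal adds QALYs at $50,000 each):")
print(nmb_table(results).to_string(index=False))
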