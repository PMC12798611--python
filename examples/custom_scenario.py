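"""Running a what-if scenario with parameter overrides.

Doubles the digital-CBT license fee and assumes a weaker remission effect,
then compares the scenario's payer NMB versus no treatment with the base
case.  Overrides use dotted paths into the parameter registry and are
re-validated, so out-of-range what-ifs fail loudly instead of silently.
"""

from gadsim import (
    ArmId,
    ParameterError,
    apply_overrides,
    default_parameters,
    expected_arm_outcome,
    nmb,
    payer_perspective,
    validate,
)

params = default_parameters()
payer = payer_perspective()


def payer_nmb_vs_none(p):
    return nmb(expected_arm_outcome(ArmId.DIGITAL_CBT, p),
               expected_arm_outcome(ArmId.NO_TREATMENT, p), payer).nmb_per_person


print(f"base case: payer NMB vs no treatment = ${payer_nmb_vs_none(params):,.2f}")

scenario = apply_overrides(params, {
    "arms.digital_cbt.treatment_cost": 800.0,
    "arms.digital_cbt.remission_prob_cycle1": 0.45,
})
assert validate(scenario) == []
print("scenario ($800 fee, 45% remission): payer NMB vs no treatment = "
      f"${payer_nmb_vs_none(scenario):,.2f}")
print("(still positive: disease-cost savings exceed the fee)")

try:
    apply_overrides(params, {"arms.digital_cbt.bogus_knob": 1.0})
except ParameterError as exc:
    print(f"unknown override rejected as expected: {exc}")
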