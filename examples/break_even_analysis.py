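"""How effective, cheap, or sticky does digital CBT need to be?

Uses the deterministic expected-value engine to locate three one-way
thresholds for the digital-CBT arm versus no treatment:

* the smallest cycle-1 remission probability with a positive NMB,
* the largest attrition rate that stays cost-beneficial,
* the largest license price at which digital CBT still beats every other
  treated arm's NMB (the crossover price).

Each threshold is reported both as the continuous root of the NMB curve
and on the reporting grid (1% for probabilities, $10 for price).
"""

from gadsim import (
    attrition_break_even,
    default_parameters,
    find_crossover_price,
    payer_perspective,
    remission_break_even,
    societal_perspective,
)

params = default_parameters()
for persp in (payer_perspective(), societal_perspective(params)):
    rem = remission_break_even(params, persp)
    att = attrition_break_even(params, persp)
    price = find_crossover_price(params, persp)
    print(f"{persp.name} perspective (willingness to pay ${persp.wtp_per_qaly:,.0f}/QALY):")
    print(f"  remission break-even: {rem.reported:.0%}  (root {rem.root:.4f})"
          "  -- below this, treating is worse than doing nothing")
    print(f"  attrition break-even: {att.reported:.0%}  (root {att.root:.4f})"
          "  -- NMB stays positive up to this dropout rate")
    print(f"  price crossover:      ${price.reported:,.0f}  (root ${price.root:,.2f})"
          "  -- above this another treatment has the higher NMB")
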