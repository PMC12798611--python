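# Methods

## Model structure

`gadsim` implements a two-state (GAD / remission) cohort state-transition
model evaluated by individual-level microsimulation. The horizon is one
year, split into two 6-month cycles; remission is absorbing (no relapse
within the horizon). Five strategies are compared on identical terms, each
with its own 20,000-person cohort: digital CBT, individual CBT, group CBT,
pharmacotherapy, and no treatment.

Cycle 1 composes two events for treated arms. With probability *q* (the
arm's attrition rate) a person leaves treatment at a Uniform(0, L) time
(L = 0.5 y); attriters forfeit the arm's remission probability for that
cycle — dropping out is modelled as receiving no clinical benefit — but
still incur disease costs for their time in GAD and a fixed share of the
treatment price. Non-attriters remit with the arm's cycle-1 probability
*p*, at a Uniform(0, L) time. In cycle 2, everyone still in GAD faces the
natural remission probability *r* (15% per cycle), attriters included;
`Conventions.attrition_second_cycle_remission=False` switches to absorbing
attrition for exploration.

## Parameters

All inputs live in one validated registry (JSON/YAML; see
`gadsim export-defaults`). The base case:

| group | field | value | units |
|---|---|---|---|
| remission (cycle 1) | digital / individual / group CBT | 0.60 | per cycle |
| | pharmacotherapy | 0.50 | per cycle |
| | no treatment & natural (cycle 2) | 0.15 | per cycle |
| attrition | digital / individual / group / pharma | 0.16 / 0.09 / 0.24 / 0.30 | during cycle 1 |
| treatment cost | digital / individual / group / pharma | 400.00 / 2,788.50 / 579.15 / 236.69 | USD per course |
| attrition cost fraction | digital; others | 1.0; 1/6 | of course price |
| healthcare | physician visit $195.25; ER $1,004.70; hospitalization $5,722 | GAD rates 4.4 visits, 5%, 5%; healthy 2.4, 2.8%, 2.8% | per cycle |
| work | disability day at $206 | GAD 21.4 days; healthy 7.8 | per cycle |
| utility | GAD 0.66; remission 0.80 | | per year |
| economics | discount 3%/yr; WTP $50,000/QALY | | |

Notes on three registry quirks, resolved deliberately: the hospitalization
entry is stored as its stated total ($5,722), not the product of its
quoted derivation; the daily wage is the stated $206, with the median
hourly wage ($27.72) kept as metadata only; the attrition cost fraction is
exactly 1/6 ("two sessions"), configurable so 2/15 can be explored. The
digital arm's fraction is 1.0 because its one-time license fee is paid
regardless of usage.

Validation returns a list of named violations (probability ranges,
GAD ≥ healthy rate ordering, utility ordering, untreated-arm constraints)
rather than raising, so broken sets can be constructed and inspected;
loading refuses to return an invalid set.

## Accounting conventions

A part-cycle remission must be credited somehow, and the choice is
consequential at these event rates. Both accrual streams take an explicit
convention (`uniform` time-proration, `cycle_start` full-cycle healthy
credit, `cycle_end` full-cycle GAD credit):

- **Costs default to `uniform`**: exposure to GAD-state utilization rates
  is prorated by actual time in state, the natural reading of resource
  use. With uniform event timing a remitter is exposed for half the cycle
  in expectation.
- **QALYs default to `cycle_start`**: utility is credited per cycle by
  state membership, the convention of cohort-level Markov accounting in
  which the transition is anchored at the cycle boundary. Under it a
  person contributes u = 0.66 or 0.80 for whole cycles, and a one-year
  GAD/remission split yields exactly 0.73.

The two streams deliberately differ in their default because they model
different things (metered resource consumption vs state-labelled utility);
either can be switched, and the test suite exercises all combinations.
Dollars are discounted cycle-anchored: cycle-1 amounts at face value,
cycle-2 amounts multiplied by 1.03^(−0.5) ≈ 0.985329; `none` disables
discounting. QALYs are never discounted. Treatment cost is incurred in
cycle 1 (undiscounted).

## Engines

- **Microsimulation**: vectorized per-person draws. Per-arm substreams
  derive from `SeedSequence([master_seed, sha256(arm_name) mod 2^31])`, so
  adding an arm never perturbs another arm's draws, and all uniforms are
  drawn unconditionally in fixed order — under common random numbers,
  raising a remission probability can only move a person's remission
  earlier (monotone coupling, tested).
- **Expected-value engine**: closed-form occupancy expectations. With
  within-cycle credit *c*, a cycle with hazard *p* contributes expected
  GAD fraction 1 − p(1 − c) among those at risk; cycle 1 composes
  attrition as E[f₁] = q + (1 − q)(1 − p(1 − c)), and cycle 2 applies the
  natural hazard to the still-in-GAD mass. The Monte Carlo means must
  match these expectations within 3 standard errors for every arm (tested
  against an independent exhaustive enumeration of the outcome tree).

Disease-cost accrual likewise has two modes: `expected` (rate × unit
cost, the default) and `stochastic` (Poisson visit/day counts, Bernoulli
ER/hospitalization indicators with prorated means — a canonical count
model chosen because only mean rates are specified; ER and hospitalization
are drawn independently). The modes agree in expectation and within 3
standard errors at n = 20,000 (tested).

All reported thresholds (break-even remission/attrition, crossover price)
use the expected-value engine: near a root, Monte Carlo noise would make
an integer-percent answer seed-dependent. Stochastic confirmation is a
test, not the reported value. Roots are located by Brent's method after a
monotone coarse scan; reported values are the extreme grid point (1% for
probabilities, $10 for price) at which the NMB condition holds, matching
how such thresholds are conventionally quoted.

## What the simulation does and does not emulate

The generator reproduces the stochastic structure the analysis assumes:
Bernoulli attrition and remission, uniform within-cycle event timing,
independent individuals, homogeneous cohorts. It does **not** model
relapse, comorbidity costs, patient heterogeneity or treatment preference,
time-varying hazards, correlated healthcare events, or anything beyond the
12-month horizon — passing tests therefore validate the accounting and the
model's internal logic, not the external realism of those simplifications.
Costs omitted by design: out-of-pocket, travel, and time costs of
attending care.

## Numerical choices and degenerate inputs

- Cohort aggregation is exact summation of per-person components;
  `total_cost` is defined as the sum of the treatment/healthcare/work
  totals, so conservation holds bit-for-bit.
- A remission probability of 0 everywhere yields occupancy identically 1,
  mean QALYs exactly 0.66, and disease cost exactly
  5,603.835 × (1 + 1.03^(−0.5)) per person.
- Break-even search requires a monotone NMB over the scan grid and reports
  "absent" (None) when no sign change exists, e.g. an attrition sweep for
  a treatment no better than natural remission.
- The payer price-crossover is linear with slope exactly −1 $/person per
  $ of price (the digital fee is paid by completers and attriters alike,
  and QALYs are price-invariant), so its root is found to $0.01 and then
  snapped to the $10 reporting grid.
- Sweep grids default to 0–80% in 1% steps for probabilities and
  $0–$3,000 in $10 steps for price.

## Known limitations

Beyond the structural exclusions above: the two QALY/cost timing defaults
are a modelling judgement, not an empirical estimate — under `uniform`
QALY timing, arm QALY totals drop by roughly 2–3% (half a cycle of utility
difference for each within-cycle remitter), and under `cycle_start` cost
timing arm costs drop by 4–8%; conclusions about the *ranking* of
strategies are unchanged across all combinations, but absolute totals and
the price-crossover location shift. The attrition break-even in the
societal perspective is particularly sensitive to whether attriters retain
second-cycle natural remission (69% under the default rule vs 61% under
absorbing attrition). Problem sizes follow the base case throughout:
20,000 persons per arm for simulated quantities, with thresholds computed
analytically.
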