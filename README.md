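# gadsim

A Markov cohort microsimulation for the cost-effectiveness and cost-benefit
of treatments for **generalized anxiety disorder (GAD)** in US adults with
moderate-to-severe symptoms (GAD-7 ≥ 10). The model compares five
strategies over a 12-month horizon — fully automated digital CBT,
therapist-delivered individual CBT, group CBT, pharmacotherapy (generic
SSRI plus a management visit), and no treatment — from both a private-payer
and a societal perspective, in 2020 US dollars.

It is intended for health-economics practitioners and methods-minded
clinicians who want a transparent, fully tested, reconfigurable
implementation of this class of decision model: every parameter is a
visible field in a validated registry, every accounting convention is an
explicit switch, and every reported number is reproducible from a seed.

## The model

Each simulated person starts in the GAD state and can move once,
irreversibly, to remission (no relapse within the horizon). Time is two
6-month cycles. In cycle 1 a person in a treated arm either drops out
(attrition probability *q*, at a Uniform(0, 6 mo) time, forfeiting the
treatment's remission chance) or completes treatment and remits with the
arm's probability *p* at a uniform within-cycle time. In cycle 2 everyone
still in GAD — attriters included — remits with the natural probability
*r* = 15%.

Per person the model accrues:

- **treatment cost** — the course price; attriters pay a fraction of it
  (all of it for digital CBT, whose one-time license fee is sunk; 1/6 for
  the other treated arms);
- **disease cost** — physician visits, ER visits, hospitalizations and
  disability days, each with a GAD-state and a healthy-state rate prorated
  by time in state and priced at registry unit costs; cycle-2 dollars are
  discounted at 3%/year;
- **QALYs** — time-weighted health utility, 0.66 in GAD and 0.80 in
  remission, undiscounted.

Strategies are compared by per-person **net monetary benefit**,

> NMB = (cost_comparator − cost_focal) + λ · (QALY_focal − QALY_comparator),

with λ = $0/QALY for the payer perspective and λ = $50,000/QALY for the
societal perspective. One-way sensitivity sweeps vary a single registry
field over a grid and locate break-even points (NMB = 0) and the crossover
price (the largest digital-CBT price at which it still has the highest NMB
of all treated arms) with a deterministic expected-value engine; a
common-random-numbers microsimulation engine confirms the curves.

## Worked example

`python examples/baseline_run.py` simulates all five arms (n = 20,000
each, seed 1) and prints:

```
            arm  total_cost_millions  total_qalys  ...  mean_cost  mean_qalys
    digital_cbt               177.90     14722.15  ...    8895.04      0.7361
 individual_cbt               217.67     14825.75  ...   10883.55      0.7413
      group_cbt               183.36     14604.27  ...    9168.02      0.7302
pharmacotherapy               188.37     14311.32  ...    9418.38      0.7156
   no_treatment               203.37     13799.55  ...   10168.62      0.6900

     comparator   payer  societal
 individual_cbt 1988.51   1729.51
      group_cbt  272.98    567.68
pharmacotherapy  523.35   1550.42
   no_treatment 1273.58   3580.08
```

Reading: digital CBT has the lowest 12-month total cost ($177.9m for
20,000 people) because remission sharply cuts disease costs — note the
work-cost column dominates healthcare — and the second-highest QALY total.
Its NMB is positive against every alternative in both perspectives: e.g.
per person it saves $1,273.58 relative to doing nothing from a payer's
point of view, rising to $3,580.08 when QALY gains are valued at
$50,000 each.

`python examples/break_even_analysis.py` prints the one-way thresholds
(payer: 28% remission break-even, 60% attrition break-even, $680 price
crossover; societal: 23%, 69%, $1,000), and
`python examples/custom_scenario.py` shows dotted-path what-if overrides.

The same analyses are available from a shell:

```bash
gadsim baseline --out runs/base --seed 1
gadsim sensitivity remission --perspective payer --out runs/rem
gadsim export-defaults params.json   # edit, then: gadsim baseline --params params.json ...
```

Every run writes a `manifest.json` (seed, engine, conventions, parameter
fingerprint) from which the bundle reproduces byte-for-byte.

## Layout

- `src/gadsim/parameters.py` — validated parameter registry, JSON/YAML I/O,
  dotted-path overrides
- `src/gadsim/cohort.py` — trajectory microsimulation + closed-form
  occupancy oracle
- `src/gadsim/economics.py` — dollars and QALYs, per person and per arm
- `src/gadsim/cea.py` — NMB algebra and report tables
- `src/gadsim/sensitivity.py` — sweeps, break-even and crossover search
- `src/gadsim/reporting.py`, `src/gadsim/cli.py` — run bundles, manifests,
  CLI
- `docs/methods.md` — model assumptions, conventions, and limitations
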