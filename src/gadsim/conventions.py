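"""Accounting conventions for the two-cycle Markov microsimulation.

The model draws a remission time for every individual who remits, but the
reported economic quantities depend on how a part-cycle remission is
credited.  Three conventions are supported for each of the two accrual
streams (dollars and QALYs):

``uniform``
    Time-prorated: a person who remits at time *t* inside a cycle spends
    the fraction ``(t - cycle_start) / cycle_length`` of that cycle in the
    GAD state.  With uniform within-cycle remission timing the expected
    credit is half a cycle.
``cycle_start``
    State-per-cycle accounting: a person counts as healthy for the whole
    cycle in which they remit (the transition is anchored at the cycle
    boundary before the event).
``cycle_end``
    The mirror image: a remitter counts as in GAD for the whole remission
    cycle and healthy from the next cycle on.

Costs and QALYs may use different conventions because cycle-level state
accounting is common for utility accrual in Markov cohort models while
resource use is naturally prorated by exposure time; both are exposed so
either stream can be run under any convention.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class Timing(str, enum.Enum):
    """Within-cycle credit convention for a part-cycle remission."""

    UNIFORM = "uniform"
    CYCLE_START = "cycle_start"
    CYCLE_END = "cycle_end"

    @property
    def gad_credit(self) -> float:
        """Expected fraction of the remission cycle spent in GAD."""
        return {Timing.UNIFORM: 0.5, Timing.CYCLE_START: 0.0, Timing.CYCLE_END: 1.0}[self]


class Discounting(str, enum.Enum):
    """How future dollars are brought to present value.

    ``cycle_anchored`` leaves cycle-1 amounts undiscounted and multiplies
    cycle-2 amounts by ``(1 + r)**(-cycle_length)``; ``none`` disables
    discounting entirely.
    """

    NONE = "none"
    CYCLE_ANCHORED = "cycle_anchored"


@dataclass(frozen=True)
class Conventions:
    """Bundle of accounting switches consumed by the economics layer.

    Attributes
    ----------
    cost_timing:
        Credit convention for disease-cost exposure (default time-prorated).
    qaly_timing:
        Credit convention for utility accrual (default state-per-cycle:
        a remitter is credited the healthy utility for the full remission
        cycle).
    discounting:
        Dollar discounting convention; QALYs are never discounted.
    attrition_second_cycle_remission:
        Whether treatment attriters face the natural remission probability
        in the second cycle (default True). When False, attrition is
        absorbing: attriters stay in GAD for the whole horizon.
    """

    cost_timing: Timing = Timing.UNIFORM
    qaly_timing: Timing = Timing.CYCLE_START
    discounting: Discounting = Discounting.CYCLE_ANCHORED
    attrition_second_cycle_remission: bool = True


DEFAULT_CONVENTIONS = Conventions()
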