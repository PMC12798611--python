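"""One-way sensitivity sweeps and break-even / crossover threshold search.

A sweep varies a single parameter (dotted path into the registry) over a
grid, recomputes the focal arm's outcome at every grid point, and reports
its NMB against a fixed comparator.  Two engines are available:

* ``expected`` — the closed-form expected-value engine; deterministic,
  used for all reported thresholds so an integer-percent answer does not
  depend on a seed;
* ``stochastic`` — full microsimulation with common random numbers (the
  same master seed at every grid point), so curves are smooth in the
  swept parameter; used to confirm the expected-engine curves.

Break-even is the swept value at which NMB versus the comparator crosses
zero (located by Brent root-finding on the expected engine, or monotone
grid refinement under common random numbers); the crossover price is the
largest focal-arm price at which its NMB versus no treatment still weakly
exceeds every other treated arm's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .cea import Perspective, nmb
from .cohort import simulate_arm
from .conventions import Conventions, DEFAULT_CONVENTIONS
from .economics import ArmOutcome, ConfigurationError, aggregate_arm, expected_arm_outcome
from .parameters import ArmId, ParameterSet, TREATED_ARMS

DEFAULT_PROB_GRID = tuple(np.round(np.arange(0.0, 0.8001, 0.01), 10))
DEFAULT_PRICE_GRID = tuple(float(x) for x in range(0, 3001, 10))


@dataclass(frozen=True)
class SweepSpec:
    """Description of a one-way sweep."""

    parameter_path: str
    grid: Sequence[float]
    focal_arm: ArmId
    comparator_arm: ArmId
    perspective: Perspective
    seed: int | None = None
    engine: str = "expected"

    def __post_init__(self):
        g = list(self.grid)
        diffs = np.diff(g)
        if len(g) >= 2 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ConfigurationError("sweep grid must be strictly monotone")
        if self.engine not in ("expected", "stochastic"):
            raise ConfigurationError(f"unknown engine {self.engine!r}")
        if self.engine == "stochastic" and self.seed is None:
            raise ConfigurationError("stochastic engine requires a seed")


@dataclass(frozen=True)
class SensitivityCurve:
    spec: SweepSpec
    nmb_values: tuple[float, ...]
    reference_curves: dict[ArmId, float] = field(default_factory=dict)
    break_even: float | None = None
    crossover: float | None = None


def _outcome(
    arm: ArmId,
    params: ParameterSet,
    spec: SweepSpec,
    conventions: Conventions,
    n: int | None,
) -> ArmOutcome:
    if spec.engine == "expected":
        return expected_arm_outcome(arm, params, conventions, n=n)
    sample = simulate_arm(arm, params, seed=spec.seed, n=n, conventions=conventions)
    return aggregate_arm(sample, params, mode="expected")


def nmb_function(
    spec: SweepSpec,
    params: ParameterSet,
    conventions: Conventions = DEFAULT_CONVENTIONS,
    n: int | None = None,
) -> Callable[[float], float]:
    """NMB of the focal vs comparator arm as a function of the swept value.

    Every evaluation rebuilds the parameter set with the single override,
    so algebraic identities (e.g. price-sweep slope exactly -1 per dollar)
    emerge from the accounting rather than being assumed.
    """
    # fail fast on a bad path
    params.with_override(spec.parameter_path, list(spec.grid)[0])

    def f(value: float) -> float:
        p2 = params.with_override(spec.parameter_path, float(value))
        focal = _outcome(spec.focal_arm, p2, spec, conventions, n)
        comp = _outcome(spec.comparator_arm, p2, spec, conventions, n)
        return nmb(focal, comp, spec.perspective).nmb_per_person

    return f


def sweep(
    spec: SweepSpec,
    params: ParameterSet,
    conventions: Conventions = DEFAULT_CONVENTIONS,
    n: int | None = None,
) -> SensitivityCurve:
    """Evaluate the NMB curve over the grid plus fixed reference arms."""
    f = nmb_function(spec, params, conventions, n)
    values = tuple(f(v) for v in spec.grid)

    references: dict[ArmId, float] = {}
    for arm in TREATED_ARMS:
        if arm in (spec.focal_arm, spec.comparator_arm):
            continue
        o = _outcome(arm, params, spec, conventions, n)
        c = _outcome(spec.comparator_arm, params, spec, conventions, n)
        references[arm] = nmb(o, c, spec.perspective).nmb_per_person

    grid = np.asarray(list(spec.grid), dtype=float)
    vals = np.asarray(values)
    break_even = _sign_change_location(grid, vals)
    crossover = None
    if references:
        best_ref = max(references.values())
        above = vals >= best_ref
        if above.any() and not above.all():
            # last grid value at which the focal arm is still (weakly) best
            idx = np.where(above)[0]
            crossover = float(grid[idx[-1]]) if above[0] else float(grid[idx[0]])
    return SensitivityCurve(spec=spec, nmb_values=values, reference_curves=references,
                            break_even=break_even, crossover=crossover)


def _sign_change_location(grid: np.ndarray, vals: np.ndarray) -> float | None:
    sign = np.sign(vals)
    changes = np.where(np.diff(sign) != 0)[0]
    if len(changes) == 0:
        return None
    i = int(changes[0])
    x0, x1, y0, y1 = grid[i], grid[i + 1], vals[i], vals[i + 1]
    if y1 == y0:
        return float(x0)
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))


def find_break_even(
    spec: SweepSpec,
    params: ParameterSet,
    tolerance: float = 1e-6,
    conventions: Conventions = DEFAULT_CONVENTIONS,
    n: int | None = None,
) -> float | None:
    """Locate the swept value at which NMB crosses zero, or None.

    A coarse scan over the spec grid asserts monotonicity and brackets the
    sign change; the expected engine then refines by Brent root-finding to
    ``tolerance`` (in parameter units).  The stochastic engine refines the
    bracket by monotone bisection of grid midpoints under common random
    numbers.
    """
    f = nmb_function(spec, params, conventions, n)
    grid = np.asarray(list(spec.grid), dtype=float)
    vals = np.asarray([f(v) for v in grid])
    diffs = np.diff(vals)
    if not (np.all(diffs >= 0) or np.all(diffs <= 0)):
        raise ConfigurationError(
            "NMB is not monotone in the swept parameter over the grid")
    sign = np.sign(vals)
    changes = np.where(np.diff(sign) != 0)[0]
    if len(changes) == 0:
        return None
    i = int(changes[0])
    lo, hi = float(grid[i]), float(grid[i + 1])
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if np.sign(f(mid)) == np.sign(f(lo)) and f(lo) != 0:
            lo = mid
        else:
            hi = mid
        if spec.engine == "expected":
            # expected engine is smooth: hand the bracket to Brent
            try:
                return float(brentq(f, lo, hi, xtol=tolerance))
            except ValueError:
                break
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class ThresholdResult:
    """A located threshold: the continuous root and its grid-reported value."""

    root: float | None
    reported: float | None
    grid_step: float


def _grid_extreme_positive(
    f: Callable[[float], float],
    grid: Sequence[float],
    smallest: bool,
) -> float | None:
    """Smallest (or largest) grid value with strictly positive NMB."""
    values = [(g, f(g)) for g in grid]
    positives = [g for g, v in values if v > 0]
    if not positives:
        return None
    return min(positives) if smallest else max(positives)


def remission_break_even(
    params: ParameterSet,
    perspective: Perspective,
    conventions: Conventions = DEFAULT_CONVENTIONS,
    focal_arm: ArmId = ArmId.DIGITAL_CBT,
    grid: Sequence[float] = DEFAULT_PROB_GRID,
) -> ThresholdResult:
    """Smallest cycle-1 remission probability at which the focal arm's NMB
    versus no treatment turns positive (reported on the 1% grid)."""
    spec = SweepSpec(
        parameter_path=f"arms.{focal_arm.value}.remission_prob_cycle1",
        grid=grid, focal_arm=focal_arm, comparator_arm=ArmId.NO_TREATMENT,
        perspective=perspective,
    )
    f = nmb_function(spec, params, conventions)
    root = find_break_even(spec, params, conventions=conventions)
    reported = _grid_extreme_positive(f, grid, smallest=True)
    return ThresholdResult(root=root, reported=reported, grid_step=0.01)


def attrition_break_even(
    params: ParameterSet,
    perspective: Perspective,
    conventions: Conventions = DEFAULT_CONVENTIONS,
    focal_arm: ArmId = ArmId.DIGITAL_CBT,
    grid: Sequence[float] = DEFAULT_PROB_GRID,
) -> ThresholdResult:
    """Largest attrition probability at which the focal arm's NMB versus
    no treatment stays positive (reported on the 1% grid)."""
    spec = SweepSpec(
        parameter_path=f"arms.{focal_arm.value}.attrition_prob",
        grid=grid, focal_arm=focal_arm, comparator_arm=ArmId.NO_TREATMENT,
        perspective=perspective,
    )
    f = nmb_function(spec, params, conventions)
    root = find_break_even(spec, params, conventions=conventions)
    reported = _grid_extreme_positive(f, grid, smallest=False)
    return ThresholdResult(root=root, reported=reported, grid_step=0.01)


def find_crossover_price(
    params: ParameterSet,
    perspective: Perspective,
    conventions: Conventions = DEFAULT_CONVENTIONS,
    focal_arm: ArmId = ArmId.DIGITAL_CBT,
    grid: Sequence[float] = DEFAULT_PRICE_GRID,
) -> ThresholdResult:
    """Largest focal-arm price at which its NMB versus no treatment weakly
    exceeds every other treated arm's NMB versus no treatment.

    The focal NMB falls exactly $1 per $1 of price (both completers and
    attriters pay the full digital license fee), so the crossover is the
    root of a linear function; it is reported on the $10 grid.
    """
    competitors = [a for a in TREATED_ARMS if a is not focal_arm]
    if not competitors:
        return ThresholdResult(root=None, reported=None, grid_step=10.0)
    comp_out = {
        a: expected_arm_outcome(a, params, conventions) for a in competitors
    }
    none_out = expected_arm_outcome(ArmId.NO_TREATMENT, params, conventions)
    best_other = max(
        nmb(comp_out[a], none_out, perspective).nmb_per_person for a in competitors
    )

    path = f"arms.{focal_arm.value}.treatment_cost"

    def focal_nmb(price: float) -> float:
        p2 = params.with_override(path, float(price))
        return nmb(expected_arm_outcome(focal_arm, p2, conventions),
                   expected_arm_outcome(ArmId.NO_TREATMENT, p2, conventions),
                   perspective).nmb_per_person

    lo, hi = float(grid[0]), float(grid[-1])
    g_lo, g_hi = focal_nmb(lo) - best_other, focal_nmb(hi) - best_other
    if g_lo < 0:
        return ThresholdResult(root=None, reported=None, grid_step=10.0)
    if g_hi > 0:
        return ThresholdResult(root=None, reported=None, grid_step=10.0)  # unbounded in range
    root = float(brentq(lambda x: focal_nmb(x) - best_other, lo, hi, xtol=1e-6))
    reported = max((g for g in grid if focal_nmb(g) >= best_other), default=None)
    return ThresholdResult(root=root, reported=reported, grid_step=10.0)
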