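"""Economic accounting: discounted dollars and QALYs per person and per arm.

Three accrual streams are tracked separately and conserved in every
aggregate:

* treatment cost — paid in cycle 1; completers pay the full course price,
  attriters pay ``attrition_cost_fraction`` of it (1.0 for the digital arm,
  whose one-time license fee is sunk; 1/6 elsewhere);
* healthcare cost — physician visits, emergency-room visits and
  hospitalizations, each with a GAD-state and a healthy-state rate applied
  for the GAD and healthy fractions of each cycle (linear proration);
* work cost — disability days (absenteeism plus presenteeism folded
  together) priced at the median daily wage.

Dollars in later cycles are discounted at the annual rate anchored at cycle
boundaries; QALYs are never discounted.  ``expected`` mode accrues expected
dollars (rate x unit cost); ``stochastic`` mode draws Poisson visit/day
counts and Bernoulli ER/hospitalization indicators with the prorated means
and prices the draws — the two agree in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortSample, IndividualTrajectory, gad_fraction_matrix
from .conventions import Conventions, DEFAULT_CONVENTIONS, Discounting
from .parameters import ArmId, ParameterSet

VALID_MODES = ("expected", "stochastic")


class ConsistencyError(RuntimeError):
    """A sample and parameter set that do not belong together."""


class ConfigurationError(ValueError):
    """An invalid accounting mode or option."""


def discount_factors(params: ParameterSet, conventions: Conventions) -> np.ndarray:
    """Per-cycle present-value factors for dollar amounts."""
    g = params.globals
    if conventions.discounting is Discounting.NONE:
        return np.ones(g.n_cycles)
    k = np.arange(g.n_cycles)
    return (1.0 + g.annual_discount_rate) ** (-(k * g.cycle_length))


def _cycle_rates(params: ParameterSet) -> dict[str, tuple[float, float, float]]:
    """(healthy rate, GAD rate, unit cost) per component, per cycle."""
    d = params.disease
    return {
        "visits": (d.physician_visits_healthy, d.physician_visits_gad, d.physician_visit_cost),
        "er": (d.er_prob_healthy, d.er_prob_gad, d.er_cost),
        "hosp": (d.hosp_prob_healthy, d.hosp_prob_gad, d.hospitalization_cost),
        "days": (d.disability_days_healthy, d.disability_days_gad, d.daily_wage),
    }


@dataclass(frozen=True)
class DiseaseCost:
    healthcare: float
    work: float

    @property
    def total(self) -> float:
        return self.healthcare + self.work


@dataclass(frozen=True)
class PersonEconomics:
    """One person's discounted dollars and undiscounted QALYs."""

    treatment_cost: float
    healthcare_cost: float
    work_cost: float
    qalys: float

    @property
    def disease_cost(self) -> float:
        return self.healthcare_cost + self.work_cost

    @property
    def total_cost(self) -> float:
        return self.treatment_cost + self.healthcare_cost + self.work_cost


def treatment_cost(trajectory: IndividualTrajectory, params: ParameterSet) -> float:
    """Course price paid in cycle 1 (undiscounted under cycle anchoring)."""
    ap = params.arms[trajectory.arm]
    if trajectory.attrited:
        return ap.attrition_cost_fraction * ap.treatment_cost
    return ap.treatment_cost


def _disease_cost_arrays(
    F: np.ndarray,
    params: ParameterSet,
    disc: np.ndarray,
    mode: str,
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, np.ndarray]:
    """(healthcare, work) discounted dollars per person from occupancy ``F``."""
    if mode not in VALID_MODES:
        raise ConfigurationError(f"mode must be one of {VALID_MODES}, got {mode!r}")
    if mode == "stochastic" and rng is None:
        raise ConfigurationError("stochastic mode requires an rng")
    rates = _cycle_rates(params)
    n, n_cycles = F.shape
    healthcare = np.zeros(n)
    work = np.zeros(n)
    for k in range(n_cycles):
        f = F[:, k]
        for comp, (healthy, gad, unit) in rates.items():
            mean = healthy + f * (gad - healthy)
            if mode == "expected":
                amount = mean * unit
            elif comp in ("er", "hosp"):
                amount = (rng.random(n) < mean).astype(float) * unit
            else:
                amount = rng.poisson(mean).astype(float) * unit
            if comp == "days":
                work += disc[k] * amount
            else:
                healthcare += disc[k] * amount
    return healthcare, work


def disease_cost(
    trajectory: IndividualTrajectory,
    params: ParameterSet,
    mode: str = "expected",
    rng: np.random.Generator | None = None,
    conventions: Conventions = DEFAULT_CONVENTIONS,
) -> DiseaseCost:
    """Discounted healthcare + work dollars for one person."""
    t = np.nan if trajectory.remission_time is None else trajectory.remission_time
    F = gad_fraction_matrix(np.array([t]), trajectory.cycle_length,
                            trajectory.n_cycles, conventions.cost_timing)
    disc = discount_factors(params, conventions)
    hc, wk = _disease_cost_arrays(F, params, disc, mode, rng)
    return DiseaseCost(healthcare=float(hc[0]), work=float(wk[0]))


def qaly(
    trajectory: IndividualTrajectory,
    params: ParameterSet,
    conventions: Conventions = DEFAULT_CONVENTIONS,
) -> float:
    """Undiscounted quality-adjusted life years over the horizon."""
    g = params.globals
    fr = trajectory.gad_fractions(conventions.qaly_timing)
    return float(sum(
        g.cycle_length * (g.utility_healthy - (g.utility_healthy - g.utility_gad) * f)
        for f in fr
    ))


def person_economics(
    trajectory: IndividualTrajectory,
    params: ParameterSet,
    mode: str = "expected",
    rng: np.random.Generator | None = None,
    conventions: Conventions = DEFAULT_CONVENTIONS,
) -> PersonEconomics:
    dc = disease_cost(trajectory, params, mode=mode, rng=rng, conventions=conventions)
    return PersonEconomics(
        treatment_cost=treatment_cost(trajectory, params),
        healthcare_cost=dc.healthcare,
        work_cost=dc.work,
        qalys=qaly(trajectory, params, conventions=conventions),
    )


@dataclass(frozen=True)
class ArmOutcome:
    """Arm-level aggregate: the one-row summary of a simulated cohort."""

    arm: ArmId
    n: int
    treatment_cost_total: float
    healthcare_cost_total: float
    work_cost_total: float
    total_qalys: float
    params_fingerprint: str | None = None

    @property
    def total_cost(self) -> float:
        return self.treatment_cost_total + self.healthcare_cost_total + self.work_cost_total

    @property
    def disease_cost_total(self) -> float:
        return self.healthcare_cost_total + self.work_cost_total

    @property
    def mean_cost(self) -> float:
        return self.total_cost / self.n

    @property
    def mean_qalys(self) -> float:
        return self.total_qalys / self.n

    @classmethod
    def from_totals(cls, arm: ArmId, n: int, total_cost: float,
                    total_qalys: float) -> "ArmOutcome":
        """Build an outcome from published totals (no cost breakdown)."""
        return cls(arm=arm, n=n, treatment_cost_total=0.0,
                   healthcare_cost_total=total_cost, work_cost_total=0.0,
                   total_qalys=total_qalys, params_fingerprint=None)


def aggregate_arm(
    sample: CohortSample,
    params: ParameterSet,
    mode: str = "expected",
    rng: np.random.Generator | None = None,
    conventions: Conventions | None = None,
) -> ArmOutcome:
    """Sum per-person dollars and QALYs over a cohort (vectorized).

    The sample must have been generated under the same parameter set
    (fingerprint check); component sums are kept separate so that
    ``total_cost`` is their exact sum.
    """
    if sample.params_fingerprint != params.fingerprint():
        raise ConsistencyError(
            "cohort sample was generated under a different parameter set")
    conv = sample.conventions if conventions is None else conventions
    ap = params.arms[sample.arm]
    g = params.globals
    disc = discount_factors(params, conv)

    tc = np.where(sample.attrited,
                  ap.attrition_cost_fraction * ap.treatment_cost,
                  ap.treatment_cost)
    F_cost = sample.gad_fractions(conv.cost_timing)
    hc, wk = _disease_cost_arrays(F_cost, params, disc, mode, rng)
    F_q = sample.gad_fractions(conv.qaly_timing)
    du = g.utility_healthy - g.utility_gad
    q = g.cycle_length * (g.utility_healthy * sample.n_cycles - du * F_q.sum(axis=1))

    return ArmOutcome(
        arm=sample.arm, n=sample.n,
        treatment_cost_total=float(tc.sum()),
        healthcare_cost_total=float(hc.sum()),
        work_cost_total=float(wk.sum()),
        total_qalys=float(q.sum()),
        params_fingerprint=sample.params_fingerprint,
    )


def expected_arm_outcome(
    arm: ArmId,
    params: ParameterSet,
    conventions: Conventions = DEFAULT_CONVENTIONS,
    n: int | None = None,
) -> ArmOutcome:
    """Closed-form arm outcome (the expected-value engine).

    Identical accounting to :func:`aggregate_arm` with the Monte Carlo
    occupancy replaced by its expectation; totals scale a per-person
    expectation by ``n``.
    """
    from .cohort import expected_occupancy

    ap = params.arms[arm]
    g = params.globals
    size = g.cohort_size_per_arm if n is None else int(n)
    disc = discount_factors(params, conventions)

    tc = (1.0 - ap.attrition_prob) * ap.treatment_cost \
        + ap.attrition_prob * ap.attrition_cost_fraction * ap.treatment_cost

    occ_cost = expected_occupancy(arm, params, conventions.cost_timing, conventions)
    rates = _cycle_rates(params)
    hc = wk = 0.0
    for k, f in enumerate(occ_cost.expected_gad_fraction_by_cycle):
        for comp, (healthy, gad, unit) in rates.items():
            amount = disc[k] * (healthy + f * (gad - healthy)) * unit
            if comp == "days":
                wk += amount
            else:
                hc += amount

    occ_q = expected_occupancy(arm, params, conventions.qaly_timing, conventions)
    du = g.utility_healthy - g.utility_gad
    qy = sum(
        g.cycle_length * (g.utility_healthy - du * f)
        for f in occ_q.expected_gad_fraction_by_cycle
    )

    return ArmOutcome(
        arm=arm, n=size,
        treatment_cost_total=tc * size,
        healthcare_cost_total=hc * size,
        work_cost_total=wk * size,
        total_qalys=qy * size,
        params_fingerprint=params.fingerprint(),
    )
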