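"""Net monetary benefit under payer and societal perspectives.

For a focal strategy F compared with C at willingness-to-pay ``lambda``
per QALY, the per-person net monetary benefit is

    NMB = (mean cost of C - mean cost of F) + lambda * (mean QALY of F - mean QALY of C)

so cost savings enter positively and QALY gains are monetized.  The payer
perspective sets ``lambda = 0`` (treatment cost plus disease-cost savings
only); the societal perspective adds QALY gains valued at the configured
willingness-to-pay ($50,000/QALY by default).  The societal NMB therefore
decomposes exactly as payer NMB + lambda * dQALY per person.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .economics import ArmOutcome, ConsistencyError
from .parameters import ArmId, ParameterSet


@dataclass(frozen=True)
class Perspective:
    name: str
    wtp_per_qaly: float

    def __post_init__(self):
        if self.name == "payer" and self.wtp_per_qaly != 0:
            raise ValueError("payer perspective carries zero willingness-to-pay")


def payer_perspective() -> Perspective:
    return Perspective("payer", 0.0)


def societal_perspective(params: ParameterSet) -> Perspective:
    return Perspective("societal", params.globals.wtp_per_qaly)


def perspectives(params: ParameterSet) -> tuple[Perspective, Perspective]:
    return payer_perspective(), societal_perspective(params)


@dataclass(frozen=True)
class NMBResult:
    """Per-person net monetary benefit of ``focal_arm`` vs ``comparator_arm``."""

    focal_arm: ArmId
    comparator_arm: ArmId
    perspective: Perspective
    nmb_per_person: float
    delta_cost_per_person: float   # focal - comparator (positive = focal dearer)
    delta_qalys_per_person: float  # focal - comparator


def nmb(focal: ArmOutcome, comparator: ArmOutcome, perspective: Perspective) -> NMBResult:
    """Pairwise NMB; both outcomes must come from the same run conditions."""
    if focal.n != comparator.n:
        raise ConsistencyError(
            f"arm sizes differ ({focal.n} vs {comparator.n}); NMB is per person")
    if (focal.params_fingerprint is not None
            and comparator.params_fingerprint is not None
            and focal.params_fingerprint != comparator.params_fingerprint):
        raise ConsistencyError("outcomes computed under different parameter sets")
    d_cost = focal.mean_cost - comparator.mean_cost
    d_qaly = focal.mean_qalys - comparator.mean_qalys
    return NMBResult(
        focal_arm=focal.arm,
        comparator_arm=comparator.arm,
        perspective=perspective,
        nmb_per_person=-d_cost + perspective.wtp_per_qaly * d_qaly,
        delta_cost_per_person=d_cost,
        delta_qalys_per_person=d_qaly,
    )


def nmb_matrix(
    outcomes: Mapping[ArmId, ArmOutcome],
    focal: ArmId,
    perspective_list: Sequence[Perspective],
) -> list[NMBResult]:
    """One NMBResult per (comparator != focal, perspective), stable order."""
    missing = [a.value for a in ArmId if a not in outcomes]
    if missing:
        raise ValueError(f"missing arm outcomes: {missing}")
    results = []
    for comparator in ArmId:
        if comparator is focal:
            continue
        for persp in perspective_list:
            results.append(nmb(outcomes[focal], outcomes[comparator], persp))
    return results


def format_millions(x: float) -> str:
    """167_023_456.78 -> '167.02' (millions of dollars, two decimals)."""
    return f"{x / 1e6:.2f}"


def format_usd(x: float) -> str:
    """1836.834 -> '1,836.83'."""
    return f"{x:,.2f}"


def outcomes_table(outcomes: Mapping[ArmId, ArmOutcome]):
    """Cost/QALY summary per arm (totals in millions, 2 dp) as a DataFrame."""
    import pandas as pd

    rows = []
    for arm in ArmId:
        o = outcomes[arm]
        rows.append({
            "arm": arm.value,
            "total_cost_millions": round(o.total_cost / 1e6, 2),
            "total_qalys": round(o.total_qalys, 2),
            "treatment_cost_millions": round(o.treatment_cost_total / 1e6, 2),
            "healthcare_cost_millions": round(o.healthcare_cost_total / 1e6, 2),
            "work_cost_millions": round(o.work_cost_total / 1e6, 2),
            "mean_cost": round(o.mean_cost, 2),
            "mean_qalys": round(o.mean_qalys, 4),
        })
    return pd.DataFrame(rows)


def nmb_table(results: Iterable[NMBResult]):
    """Pairwise NMB matrix (one row per comparator, one column per perspective)."""
    import pandas as pd

    cells: dict[ArmId, dict[str, float]] = {}
    focal = None
    for r in results:
        focal = r.focal_arm
        cells.setdefault(r.comparator_arm, {})[r.perspective.name] = round(
            r.nmb_per_person, 2)
    rows = [{"comparator": comp.value, **vals} for comp, vals in cells.items()]
    df = pd.DataFrame(rows)
    df.attrs["focal"] = focal.value if focal else None
    return df


def render_tables(
    outcomes: Mapping[ArmId, ArmOutcome],
    results: Iterable[NMBResult],
) -> dict[str, str]:
    """CSV renderings of the arm-outcome and NMB tables."""
    return {
        "outcomes.csv": outcomes_table(outcomes).to_csv(index=False),
        "nmb.csv": nmb_table(results).to_csv(index=False),
    }
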