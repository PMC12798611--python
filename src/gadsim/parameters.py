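"""Model parameter registry: validation, loading, overrides, serialization.

Every input the simulator consumes lives in a single :class:`ParameterSet`:
per-arm remission/attrition/cost parameters, state-dependent disease-cost
components, health utilities, the discount rate and the willingness-to-pay
threshold.  The shipped defaults (``gadsim/data/default_parameters.json``)
encode the base-case assumptions of the analysis: five treatment arms for
moderate-to-severe generalized anxiety disorder (GAD-7 >= 10), a two-state
GAD/remission model over two 6-month cycles, 2020 US dollars.

Validation is deliberately split from construction: :func:`validate`
returns a list of violations (so deliberately-broken sets can be built in
tests), while :func:`load_parameters` refuses to return an invalid set.
"""

from __future__ import annotations

import enum
import hashlib
import json
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml
from pydantic import BaseModel, ConfigDict


class ArmId(str, enum.Enum):
    """The five treatment strategies compared by the model."""

    DIGITAL_CBT = "digital_cbt"
    INDIVIDUAL_CBT = "individual_cbt"
    GROUP_CBT = "group_cbt"
    PHARMACOTHERAPY = "pharmacotherapy"
    NO_TREATMENT = "no_treatment"


TREATED_ARMS = tuple(a for a in ArmId if a is not ArmId.NO_TREATMENT)


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=False)


class ArmParameters(_Model):
    """Arm-specific clinical and cost inputs, per 6-month cycle.

    ``attrition_cost_fraction`` is the share of the full treatment price an
    attriter still incurs: 1.0 for digital CBT (a one-time license fee paid
    regardless of usage) and 1/6 (two of the assumed sessions) for the
    therapist-delivered and pharmacotherapy arms.
    """

    remission_prob_cycle1: float
    attrition_prob: float
    treatment_cost: float
    attrition_cost_fraction: float


class DiseaseCostParameters(_Model):
    """State-dependent disease-cost components, per 6-month cycle.

    Healthcare utilization (physician visits, emergency-room visits,
    hospitalizations) and lost-productivity disability days each carry a
    GAD-state rate and a healthy-state ("none") rate; remission lowers but
    does not eliminate utilization.
    """

    physician_visit_cost: float
    physician_visits_gad: float
    physician_visits_healthy: float
    er_cost: float
    er_prob_gad: float
    er_prob_healthy: float
    hospitalization_cost: float
    hosp_prob_gad: float
    hosp_prob_healthy: float
    daily_wage: float
    disability_days_gad: float
    disability_days_healthy: float
    # documentation-only metadata; the operative value is daily_wage
    median_hourly_wage: float | None = None


class GlobalParameters(_Model):
    """Horizon, utilities, discounting and cohort-size settings."""

    utility_gad: float
    utility_healthy: float
    annual_discount_rate: float
    wtp_per_qaly: float
    cycle_length: float
    n_cycles: int
    cohort_size_per_arm: int
    natural_remission_prob: float


class ParameterSet(_Model):
    """The full validated registry consumed by every other module."""

    arms: dict[ArmId, ArmParameters]
    disease: DiseaseCostParameters
    globals: GlobalParameters

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = self.model_dump(mode="json")
        d["arms"] = {k.value if isinstance(k, ArmId) else k: v for k, v in d["arms"].items()}
        return d

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def fingerprint(self) -> str:
        """Stable sha256 hash of the canonical JSON form."""
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()

    def with_override(self, path: str, value: Any) -> "ParameterSet":
        """Return a copy with one dotted-path field replaced (unvalidated)."""
        return apply_overrides(self, {path: value})


class Violation:
    """One failed invariant: the offending field, its value, and the rule."""

    def __init__(self, field: str, value: Any, rule: str):
        self.field = field
        self.value = value
        self.rule = rule

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Violation({self.field}={self.value!r}: {self.rule})"


class ParameterError(ValueError):
    """Raised when a parameter file is malformed or fails validation."""


_DATA_FILE = Path(__file__).parent / "data" / "default_parameters.json"


def default_parameters() -> ParameterSet:
    """The base-case parameter registry shipped with the package."""
    return _from_mapping(json.loads(_DATA_FILE.read_text()))


def _from_mapping(raw: Mapping[str, Any]) -> ParameterSet:
    try:
        return ParameterSet(**raw)
    except Exception as exc:  # pydantic ValidationError -> uniform error type
        raise ParameterError(f"malformed parameter mapping: {exc}") from exc


def load_parameters(
    path: str | Path, overrides: Mapping[str, Any] | None = None
) -> ParameterSet:
    """Load a JSON/YAML parameter file, apply dotted-path overrides, validate.

    Overrides use dotted paths into the registry, e.g.
    ``arms.digital_cbt.treatment_cost``.  Unknown keys are rejected; a set
    that fails any invariant raises :class:`ParameterError` naming the
    offending field.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    text = p.read_text()
    if p.suffix.lower() in {".yaml", ".yml"}:
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    params = _from_mapping(raw)
    if overrides:
        params = apply_overrides(params, overrides)
    violations = validate(params)
    if violations:
        msgs = "; ".join(f"{v.field}={v.value!r} ({v.rule})" for v in violations)
        raise ParameterError(f"invalid parameters: {msgs}")
    return params


def apply_overrides(params: ParameterSet, overrides: Mapping[str, Any]) -> ParameterSet:
    """Apply ``{dotted.path: value}`` overrides, returning a new set.

    The result is *not* revalidated here so that sweeps and tests can build
    deliberately out-of-range sets; callers wanting safety should run
    :func:`validate` afterwards (``load_parameters`` does).
    """
    d = params.to_dict()
    for dotted, value in overrides.items():
        parts = dotted.split(".")
        node: Any = d
        for key in parts[:-1]:
            if not isinstance(node, dict) or key not in node:
                raise ParameterError(f"unknown parameter path: {dotted!r}")
            node = node[key]
        leaf = parts[-1]
        if not isinstance(node, dict) or leaf not in node:
            raise ParameterError(f"unknown parameter path: {dotted!r}")
        node[leaf] = value
    return _from_mapping(d)


def _prob(v: Iterable[tuple[str, float]]) -> Iterable[Violation]:
    for field, value in v:
        if not 0.0 <= value <= 1.0:
            yield Violation(field, value, "probability must lie in [0, 1]")


def validate(params: ParameterSet) -> list[Violation]:
    """Check every model invariant; return violations instead of raising."""
    out: list[Violation] = []
    if set(params.arms) != set(ArmId):
        out.append(
            Violation("arms", sorted(a.value for a in params.arms),
                      "exactly the five treatment arms must be present")
        )
    for arm, ap in params.arms.items():
        pre = f"arms.{arm.value}"
        out.extend(_prob([
            (f"{pre}.remission_prob_cycle1", ap.remission_prob_cycle1),
            (f"{pre}.attrition_prob", ap.attrition_prob),
            (f"{pre}.attrition_cost_fraction", ap.attrition_cost_fraction),
        ]))
        if ap.treatment_cost < 0:
            out.append(Violation(f"{pre}.treatment_cost", ap.treatment_cost,
                                 "cost must be non-negative"))
    nt = params.arms.get(ArmId.NO_TREATMENT)
    if nt is not None:
        if nt.treatment_cost != 0:
            out.append(Violation("arms.no_treatment.treatment_cost", nt.treatment_cost,
                                 "the untreated arm has zero treatment cost"))
        if nt.attrition_prob != 0:
            out.append(Violation("arms.no_treatment.attrition_prob", nt.attrition_prob,
                                 "the untreated arm has zero attrition"))

    dz = params.disease
    for field in ("physician_visit_cost", "er_cost", "hospitalization_cost", "daily_wage"):
        value = getattr(dz, field)
        if value < 0:
            out.append(Violation(f"disease.{field}", value, "cost must be non-negative"))
    out.extend(_prob([
        ("disease.er_prob_gad", dz.er_prob_gad),
        ("disease.er_prob_healthy", dz.er_prob_healthy),
        ("disease.hosp_prob_gad", dz.hosp_prob_gad),
        ("disease.hosp_prob_healthy", dz.hosp_prob_healthy),
    ]))
    for name in ("physician_visits", "disability_days"):
        g, h = getattr(dz, f"{name}_gad"), getattr(dz, f"{name}_healthy")
        if g < 0 or h < 0:
            out.append(Violation(f"disease.{name}", (g, h), "rates must be non-negative"))
        if g < h:
            out.append(Violation(f"disease.{name}_gad", g,
                                 "GAD-state rate must be >= healthy-state rate"))
    for name in ("er_prob", "hosp_prob"):
        if getattr(dz, f"{name}_gad") < getattr(dz, f"{name}_healthy"):
            out.append(Violation(f"disease.{name}_gad", getattr(dz, f"{name}_gad"),
                                 "GAD-state rate must be >= healthy-state rate"))

    g = params.globals
    if not 0.0 <= g.utility_gad <= g.utility_healthy <= 1.0:
        out.append(Violation("globals.utility_gad", (g.utility_gad, g.utility_healthy),
                             "require 0 <= utility_gad <= utility_healthy <= 1"))
    if g.annual_discount_rate < 0:
        out.append(Violation("globals.annual_discount_rate", g.annual_discount_rate,
                             "discount rate must be non-negative"))
    out.extend(_prob([("globals.natural_remission_prob", g.natural_remission_prob)]))
    if g.cycle_length <= 0 or g.n_cycles <= 0:
        out.append(Violation("globals.cycle_length", (g.cycle_length, g.n_cycles),
                             "horizon must be positive"))
    if g.cohort_size_per_arm <= 0:
        out.append(Violation("globals.cohort_size_per_arm", g.cohort_size_per_arm,
                             "cohort size must be positive"))
    return out


def export_registry_csv(params: ParameterSet, path: str | Path) -> None:
    """Write a flat field/value/units CSV of the registry for documentation."""
    import pandas as pd

    rows: list[dict[str, Any]] = []
    units = {
        "remission_prob_cycle1": "probability per cycle",
        "attrition_prob": "probability during cycle 1",
        "treatment_cost": "USD per course",
        "attrition_cost_fraction": "fraction of treatment cost",
    }
    for arm, ap in params.arms.items():
        for field, value in ap.model_dump().items():
            rows.append({"field": f"arms.{arm.value}.{field}", "value": value,
                         "units": units.get(field, "")})
    disease_units = {
        "physician_visit_cost": "USD per visit", "physician_visits_gad": "visits per cycle",
        "physician_visits_healthy": "visits per cycle", "er_cost": "USD per visit",
        "er_prob_gad": "probability per cycle", "er_prob_healthy": "probability per cycle",
        "hospitalization_cost": "USD per stay", "hosp_prob_gad": "probability per cycle",
        "hosp_prob_healthy": "probability per cycle", "daily_wage": "USD per disability day",
        "disability_days_gad": "days per cycle", "disability_days_healthy": "days per cycle",
        "median_hourly_wage": "USD per hour (metadata)",
    }
    for field, value in params.disease.model_dump().items():
        rows.append({"field": f"disease.{field}", "value": value,
                     "units": disease_units.get(field, "")})
    global_units = {
        "utility_gad": "utility per year", "utility_healthy": "utility per year",
        "annual_discount_rate": "fraction per year", "wtp_per_qaly": "USD per QALY",
        "cycle_length": "years", "n_cycles": "count", "cohort_size_per_arm": "persons",
        "natural_remission_prob": "probability per cycle",
    }
    for field, value in params.globals.model_dump().items():
        rows.append({"field": f"globals.{field}", "value": value,
                     "units": global_units.get(field, "")})
    pd.DataFrame(rows).to_csv(path, index=False)
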