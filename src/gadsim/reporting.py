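"""Run orchestration: baseline and sensitivity bundles with manifests.

A *run* takes a validated parameter set, a master seed and the accounting
conventions, executes the requested analysis, and writes a deterministic
bundle of text outputs into a directory:

* ``outcomes.csv``   — one row per arm (total cost in millions, total QALYs,
  cost breakdown);
* ``nmb.csv``        — the pairwise NMB matrix for the focal arm under both
  perspectives;
* ``sensitivity.csv`` / ``thresholds.json`` — for sweep runs;
* ``manifest.json``  — everything needed to reproduce the bundle
  byte-for-byte: command, seed, engine, conventions, parameter fingerprint
  and overrides, package version;
* ``summary.txt``    — a short human-readable account.

Rerunning with the same manifest inputs reproduces every output exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from . import __version__
from .cea import (
    format_usd,
    nmb_matrix,
    nmb_table,
    outcomes_table,
    payer_perspective,
    perspectives,
    societal_perspective,
)
from .cohort import arm_substream_seed, simulate_arm
from .conventions import Conventions, DEFAULT_CONVENTIONS
from .economics import ArmOutcome, aggregate_arm, expected_arm_outcome
from .parameters import ArmId, ParameterSet
from .sensitivity import (
    attrition_break_even,
    find_crossover_price,
    remission_break_even,
)

log = logging.getLogger("gadsim")

SWEEP_NAMES = ("remission", "price", "attrition")


@dataclass(frozen=True)
class RunConfig:
    """Everything that determines a run's outputs."""

    params: ParameterSet
    seed: int = 1
    engine: str = "stochastic"            # stochastic | expected
    conventions: Conventions = DEFAULT_CONVENTIONS
    n: int | None = None                  # per-arm cohort size override
    focal_arm: ArmId = ArmId.DIGITAL_CBT
    overrides: Mapping[str, Any] = field(default_factory=dict)
    params_file: str | None = None


def manifest_dict(config: RunConfig, command: str, outputs: Sequence[str]) -> dict:
    conv = config.conventions
    return {
        "command": command,
        "package_version": __version__,
        "seed": config.seed,
        "engine": config.engine,
        "n_per_arm": config.n or config.params.globals.cohort_size_per_arm,
        "focal_arm": config.focal_arm.value,
        "conventions": {
            "cost_timing": conv.cost_timing.value,
            "qaly_timing": conv.qaly_timing.value,
            "discounting": conv.discounting.value,
            "attrition_second_cycle_remission": conv.attrition_second_cycle_remission,
        },
        "params_file": config.params_file,
        "overrides": dict(config.overrides),
        "params_fingerprint": config.params.fingerprint(),
        "arm_seed_substreams": {
            a.value: arm_substream_seed(config.seed, a) for a in ArmId
        },
        "outputs": list(outputs),
    }


def compute_outcomes(config: RunConfig) -> dict[ArmId, ArmOutcome]:
    """Simulate (or analytically evaluate) all five arms."""
    outcomes: dict[ArmId, ArmOutcome] = {}
    for arm in ArmId:
        if config.engine == "expected":
            outcomes[arm] = expected_arm_outcome(
                arm, config.params, config.conventions, n=config.n)
        else:
            sample = simulate_arm(arm, config.params, seed=config.seed,
                                  n=config.n, conventions=config.conventions)
            outcomes[arm] = aggregate_arm(sample, config.params, mode="expected")
        log.info("arm %s: mean cost %s, mean QALYs %.4f",
                 arm.value, format_usd(outcomes[arm].mean_cost),
                 outcomes[arm].mean_qalys)
    return outcomes


def run_baseline(config: RunConfig, out_dir: str | Path,
                 write_trajectories: bool = False, force: bool = False) -> Path:
    """Simulate all five arms; write outcome, NMB and manifest files."""
    out = _prepare_dir(out_dir, force)
    outcomes = compute_outcomes(config)
    results = nmb_matrix(outcomes, config.focal_arm, list(perspectives(config.params)))

    t2 = outcomes_table(outcomes)
    t3 = nmb_table(results)
    t2.to_csv(out / "outcomes.csv", index=False)
    t3.to_csv(out / "nmb.csv", index=False)

    files = ["outcomes.csv", "nmb.csv", "summary.txt", "manifest.json"]
    if write_trajectories and config.engine != "expected":
        import pandas as pd

        frames = [
            simulate_arm(arm, config.params, seed=config.seed, n=config.n,
                         conventions=config.conventions).to_frame()
            for arm in ArmId
        ]
        pd.concat(frames, ignore_index=True).to_csv(out / "trajectories.csv", index=False)
        files.append("trajectories.csv")

    lines = [
        f"gadsim baseline run (engine={config.engine}, seed={config.seed}, "
        f"n={config.n or config.params.globals.cohort_size_per_arm} per arm)",
        "",
        "Arm outcomes (12-month totals):",
        t2.to_string(index=False),
        "",
        f"Net monetary benefit per person, focal arm = {config.focal_arm.value}:",
        t3.to_string(index=False),
        "",
    ]
    (out / "summary.txt").write_text("\n".join(lines))
    _write_manifest(out, config, "baseline", files)
    return out


def run_sensitivity(config: RunConfig, sweep_name: str, perspective_name: str,
                    out_dir: str | Path, force: bool = False) -> Path:
    """Run one named sweep (remission | price | attrition) for a perspective."""
    if sweep_name not in SWEEP_NAMES:
        raise ValueError(
            f"unknown sweep {sweep_name!r}; options: {', '.join(SWEEP_NAMES)}")
    if perspective_name == "payer":
        persp = payer_perspective()
    elif perspective_name == "societal":
        persp = societal_perspective(config.params)
    else:
        raise ValueError("perspective must be 'payer' or 'societal'")

    out = _prepare_dir(out_dir, force)
    params, conv = config.params, config.conventions

    from .sensitivity import DEFAULT_PRICE_GRID, DEFAULT_PROB_GRID, SweepSpec, sweep

    if sweep_name == "remission":
        th = remission_break_even(params, persp, conv, config.focal_arm)
        path = f"arms.{config.focal_arm.value}.remission_prob_cycle1"
        grid = DEFAULT_PROB_GRID
        kind = "break_even"
    elif sweep_name == "attrition":
        th = attrition_break_even(params, persp, conv, config.focal_arm)
        path = f"arms.{config.focal_arm.value}.attrition_prob"
        grid = DEFAULT_PROB_GRID
        kind = "break_even"
    else:
        th = find_crossover_price(params, persp, conv, config.focal_arm)
        path = f"arms.{config.focal_arm.value}.treatment_cost"
        grid = DEFAULT_PRICE_GRID
        kind = "crossover"

    spec = SweepSpec(parameter_path=path, grid=grid, focal_arm=config.focal_arm,
                     comparator_arm=ArmId.NO_TREATMENT, perspective=persp)
    curve = sweep(spec, params, conv, n=config.n)

    import pandas as pd

    df = pd.DataFrame({"value": list(grid), "focal_nmb": list(curve.nmb_values)})
    for arm, ref in curve.reference_curves.items():
        df[f"nmb_{arm.value}"] = ref
    df.to_csv(out / "sensitivity.csv", index=False)

    thresholds = {
        "sweep": sweep_name,
        "perspective": persp.name,
        "engine": "expected",
        "seed": config.seed,
        "parameter_path": path,
        kind: th.reported,
        f"{kind}_root": th.root,
        "grid_step": th.grid_step,
    }
    (out / "thresholds.json").write_text(json.dumps(thresholds, indent=2) + "\n")
    _write_manifest(out, config, f"sensitivity:{sweep_name}:{persp.name}",
                    ["sensitivity.csv", "thresholds.json", "manifest.json"])
    return out


def _prepare_dir(out_dir: str | Path, force: bool) -> Path:
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out} is not empty (use force to overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_manifest(out: Path, config: RunConfig, command: str,
                    files: Sequence[str]) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest_dict(config, command, files), indent=2, sort_keys=True)
        + "\n")
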