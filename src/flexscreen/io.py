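"""Parameter-file readers/writers, run configuration and pipeline drivers.

On-disk layout of a parameter-file directory (all plain CSV/JSON, '.' decimal
separator regardless of locale):

* ``config.json`` — grid definition, cohort size, screening unit cost;
* ``incidence.csv`` — columns ``age_low, status, iota`` (status 'S'/'NS');
* ``stages.csv`` — columns ``age_low, status, stage, q``;
* ``survival.csv`` — columns ``age_low, stage, t, lam, pi_bc, pi_other``
  (stage -1 rows describe cancer-free background mortality and carry zero
  cause-split columns);
* ``costs_first_year.csv`` / ``costs_years_2_to_5.csv`` /
  ``costs_final_year.csv`` — the three phase cost tables, rows = age bands,
  columns ``stage_0..stage_4``.

Loading validates everything and reports *all* violations at once; nothing
is silently repaired.  Monetary outputs are rounded to 2 decimals only at
presentation time, never internally.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_engine import ComparisonRow, comparison_row, evaluate_policy
from .cost_rules import CostModel
from .model_core import (
    AgeGrid,
    N_STAGES,
    CauseJointLaw,
    ConditionalStageDistribution,
    IncidenceSchedule,
    ModelInputs,
    PolicyVector,
    SurvivalLaw,
    ValidationError,
    validate_inputs,
)
from .scenario_builder import (
    SENSITIVITY_KINDS,
    Scenario,
    apply_sensitivity,
    build_standard_scenarios,
)

__all__ = [
    "RunConfig",
    "save_inputs",
    "load_inputs",
    "load_overrides",
    "load_scenario_spec",
    "save_scenario_spec",
    "compare_scenarios",
    "comparison_frame",
    "run_comparison",
    "run_sensitivity",
    "write_comparison_csv",
    "write_manifest",
]

log = logging.getLogger("flexscreen")

_FLOAT_FMT = "%.17g"  # lossless round-trip for float64

TABLE_COLUMNS = [
    "policy",
    "EC",
    "ET",
    "EC_per_ET",
    "incremental_cost",
    "ICER",
    "bc_deaths",
]

_COST_FILES = {
    "c1": "costs_first_year.csv",
    "c2": "costs_years_2_to_5.csv",
    "c3": "costs_final_year.csv",
}


@dataclass(frozen=True)
class RunConfig:
    """Resolved paths and switches for one pipeline run."""

    input_dir: Path
    output_dir: Path
    overrides_path: Path | None = None
    seed: int = 0
    log_level: str = "INFO"


def save_inputs(inputs: ModelInputs, directory: str | Path) -> Path:
    """Write a complete parameter-file set; returns the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grid = inputs.age_grid

    config = {
        "n_groups": grid.n_groups,
        "start_age": grid.start_age,
        "horizon_age": grid.horizon_age,
        "n0": inputs.n0,
        "screening_unit_cost": inputs.cost_model.screening_unit_cost,
    }
    (directory / "config.json").write_text(json.dumps(config, indent=2) + "\n")

    rows = []
    for j in range(grid.n_groups):
        for s, label in enumerate(("NS", "S")):
            rows.append((grid.lower_age(j), label, inputs.incidence.iota[j, s]))
    pd.DataFrame(rows, columns=["age_low", "status", "iota"]).to_csv(
        directory / "incidence.csv", index=False, float_format=_FLOAT_FMT
    )

    rows = []
    for j in range(grid.n_groups):
        for s, label in enumerate(("NS", "S")):
            for k in range(N_STAGES):
                rows.append((grid.lower_age(j), label, k, inputs.stages.q[j, s, k]))
    pd.DataFrame(rows, columns=["age_low", "status", "stage", "q"]).to_csv(
        directory / "stages.csv", index=False, float_format=_FLOAT_FMT
    )

    rows = []
    n_t = inputs.survival.n_t
    for j in range(grid.n_groups):
        for k in range(-1, N_STAGES):
            lam_row = inputs.survival.mass(j, k)
            for t in range(n_t):
                if lam_row[t] == 0.0 and t > grid.t_max(j):
                    continue
                bc = other = 0.0
                if k >= 0:
                    bc = inputs.causes.pi[j, k, t, 0]
                    other = inputs.causes.pi[j, k, t, 1]
                rows.append((grid.lower_age(j), k, t, lam_row[t], bc, other))
    pd.DataFrame(
        rows, columns=["age_low", "stage", "t", "lam", "pi_bc", "pi_other"]
    ).to_csv(directory / "survival.csv", index=False, float_format=_FLOAT_FMT)

    frames = inputs.cost_model.to_frames()
    for key, fname in _COST_FILES.items():
        frames[key].to_csv(directory / fname, float_format=_FLOAT_FMT)
    return directory


def _read_csv(path: Path, problems: list[str]) -> pd.DataFrame | None:
    if not path.exists():
        problems.append(f"{path.name}: file not found")
        return None
    try:
        # round_trip parsing: reloaded float64 values are bit-identical
        return pd.read_csv(path, float_precision="round_trip")
    except Exception as err:  # parse errors name the file
        problems.append(f"{path.name}: parse error: {err}")
        return None


def load_inputs(directory: str | Path) -> ModelInputs:
    """Load and fully validate a parameter-file directory.

    Raises :class:`ValidationError` carrying *every* problem found, not just
    the first.
    """
    directory = Path(directory)
    problems: list[str] = []

    cfg_path = directory / "config.json"
    if not cfg_path.exists():
        raise ValidationError(f"{cfg_path.name}: file not found")
    try:
        config = json.loads(cfg_path.read_text())
    except json.JSONDecodeError as err:
        raise ValidationError(f"{cfg_path.name}: line {err.lineno}, column {err.colno}: {err.msg}")

    grid = AgeGrid(
        n_groups=int(config["n_groups"]),
        start_age=int(config.get("start_age", 46)),
        horizon_age=int(config.get("horizon_age", 100)),
    )
    n_t = grid.n_t

    inc_df = _read_csv(directory / "incidence.csv", problems)
    stg_df = _read_csv(directory / "stages.csv", problems)
    srv_df = _read_csv(directory / "survival.csv", problems)
    cost_frames = {
        key: _read_csv(directory / fname, problems) for key, fname in _COST_FILES.items()
    }
    if problems:
        raise ValidationError(problems)

    status_idx = {"NS": 0, "S": 1}

    iota = np.full((grid.n_groups, 2), np.nan)
    for _, row in inc_df.iterrows():
        iota[grid.group_of_age(int(row.age_low)), status_idx[row.status]] = row.iota
    if np.isnan(iota).any():
        problems.append("incidence.csv: missing (age_low, status) rows")

    q = np.full((grid.n_groups, 2, N_STAGES), np.nan)
    for _, row in stg_df.iterrows():
        q[grid.group_of_age(int(row.age_low)), status_idx[row.status], int(row.stage)] = row.q
    if np.isnan(q).any():
        problems.append("stages.csv: missing (age_low, status, stage) rows")

    lam = np.zeros((grid.n_groups, N_STAGES + 1, n_t))
    pi = np.zeros((grid.n_groups, N_STAGES, n_t, 2))
    for _, row in srv_df.iterrows():
        j = grid.group_of_age(int(row.age_low))
        k = int(row.stage)
        t = int(row.t)
        if t >= n_t:
            problems.append(f"survival.csv: t={t} beyond the grid horizon at age {row.age_low}")
            continue
        lam[j, k + 1, t] = row.lam
        if k >= 0:
            pi[j, k, t, 0] = row.pi_bc
            pi[j, k, t, 1] = row.pi_other

    cost_model = None
    try:
        cost_model = CostModel.from_frames(
            cost_frames["c1"],
            cost_frames["c2"],
            cost_frames["c3"],
            screening_unit_cost=float(config.get("screening_unit_cost", 30.0)),
        )
    except ValidationError as err:
        problems.extend(err.violations)

    if problems:
        raise ValidationError(problems)

    inputs = ModelInputs(
        age_grid=grid,
        incidence=IncidenceSchedule(iota),
        stages=ConditionalStageDistribution(q),
        survival=SurvivalLaw(lam),
        causes=CauseJointLaw(pi),
        cost_model=cost_model,
        n0=float(config.get("n0", 100_000.0)),
    )
    problems = validate_inputs(inputs)
    if problems:
        raise ValidationError(problems)
    return inputs


def save_overrides(overrides: dict[int, float], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({str(j): v for j, v in overrides.items()}, indent=2) + "\n"
    )


def load_overrides(path: str | Path) -> dict[int, float]:
    """Older-extension incidence overrides: JSON map group index -> rate."""
    data = json.loads(Path(path).read_text())
    return {int(j): float(v) for j, v in data.items()}


def load_scenario_spec(path: str | Path) -> "ScenarioSpec":
    """Read a declarative scenario transform from a JSON or YAML file."""
    import yaml

    from .scenario_builder import ScenarioSpec

    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValidationError(f"{Path(path).name}: scenario config must be a mapping")
    return ScenarioSpec.from_dict(data)


def save_scenario_spec(spec: "ScenarioSpec", path: str | Path) -> None:
    import yaml

    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(spec.to_dict(), indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# Pipeline drivers
# ---------------------------------------------------------------------------

def compare_scenarios(
    reference: Scenario, alternatives: list[Scenario]
) -> list[ComparisonRow]:
    """Comparison rows where each scenario carries its own transformed inputs."""
    ref_result = evaluate_policy(reference.inputs, reference.policy)
    rows = [comparison_row(reference.name, ref_result, None)]
    for scen in alternatives:
        result = evaluate_policy(scen.inputs, scen.policy)
        rows.append(comparison_row(scen.name, result, ref_result))
    return rows


def comparison_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "policy": r.label,
                "EC": r.ec,
                "ET": r.et,
                "EC_per_ET": r.ratio,
                "incremental_cost": r.incremental_cost,
                "ICER": r.icer,
                "bc_deaths": r.bc_deaths,
            }
            for r in rows
        ],
        columns=TABLE_COLUMNS,
    )


def write_comparison_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Presentation rounding only: money and years to 2 decimals on disk."""
    out = frame.copy()
    for col in ("EC", "ET", "EC_per_ET", "incremental_cost", "ICER", "bc_deaths"):
        out[col] = out[col].map(lambda v: "" if v is None or pd.isna(v) else f"{v:.2f}")
    out.to_csv(path, index=False)


def run_comparison(
    inputs: ModelInputs,
    older_overrides: dict[int, float],
    base_policy: PolicyVector | None = None,
) -> pd.DataFrame:
    """Four-row policy comparison: current policy + the three extensions."""
    reference, alternatives = build_standard_scenarios(
        inputs, older_overrides, base_policy
    )
    return comparison_frame(compare_scenarios(reference, alternatives))


def run_sensitivity(
    inputs: ModelInputs,
    older_overrides: dict[int, float],
    base_policy: PolicyVector | None = None,
) -> dict[str, pd.DataFrame]:
    """One comparison table per sensitivity variant, mirroring the main table."""
    reference, alternatives = build_standard_scenarios(
        inputs, older_overrides, base_policy
    )
    out: dict[str, pd.DataFrame] = {}
    for kind in SENSITIVITY_KINDS:
        ref_v = apply_sensitivity(reference, kind)
        alts_v = [apply_sensitivity(s, kind) for s in alternatives]
        out[kind] = comparison_frame(compare_scenarios(ref_v, alts_v))
    return out


def sensitivity_filename(kind: str) -> str:
    safe = (
        kind.replace("+", "_plus_")
        .replace("-", "_minus_")
        .replace("%", "pct")
        .replace(".", "_")
    )
    return f"sensitivity_{safe}.csv"


def write_manifest(
    output_dir: str | Path, input_dir: str | Path, seed: int | None = None
) -> Path:
    """JSON run manifest: content hash of every input file, seed, version."""
    input_dir = Path(input_dir)
    hashes = {}
    for path in sorted(input_dir.glob("*")):
        if path.is_file():
            hashes[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "package": "flexscreen",
        "version": __version__,
        "inputs": hashes,
        "seed": seed,
    }
    out = Path(output_dir) / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2) + "\n")
    return out
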