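"""Screening-policy scenarios and one-way sensitivity variants.

A scenario is a transformed copy of the baseline parameter set plus the
policy it is evaluated under.  The flexibility of the model lives here:
extending screening to new age groups does not require new survival or cost
estimates — only the incidence rates and conditional stage distributions of
the affected groups are modelled, by borrowing from the closest groups whose
behaviour under screening is observed.

Built-in scenarios (relative to the current Finnish policy, screening ages
50-69):

* **younger extension** (screen from 46): the newly screened groups 46-47 and
  48-49 take the stage distribution observed for 50-51 resp. 52-53 under the
  current policy; 50-51 — no longer the first screen — takes 52-53's
  distribution.  Incidence is adjusted by +28% (46-47, first screen), +24.7%
  (48-49) and -11.9% (50-51 loses its first-screen prevalence peak).
* **older extension** (screen to 73): the newly screened groups 70-71 and
  72-73 take the stage distribution of 68-69; every group above shifts the
  baseline old-age stage profile down by two groups (74-75 gets baseline
  70-71's, 76-77 gets 72-73's, ...).  Post-screening incidence for the
  groups above 69 follows an externally supplied pattern (in Finland's case
  the decline observed in Sweden, where screening runs to 74); it is a
  config input, never hard-coded.
* **both**: younger then older; the transformed age ranges are disjoint so
  the order is immaterial.

Sensitivity variants perturb exactly one ingredient of a built scenario:
all *modelled* incidence rates +/-10%, all treatment costs +10% or +50%, or
0.02 of conditional probability moved between localized and regional stages
for the modelled groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from .model_core import (
    AgeGrid,
    ConditionalStageDistribution,
    IncidenceSchedule,
    ModelInputs,
    PolicyVector,
    ValidationError,
    require_valid,
)

__all__ = [
    "Scenario",
    "ScenarioSpec",
    "SENSITIVITY_KINDS",
    "build_younger_extension",
    "build_older_extension",
    "build_both_extension",
    "build_standard_scenarios",
    "apply_sensitivity",
]

#: incidence adjustments for the younger extension (multiplicative).
YOUNGER_FIRST_SCREEN_FACTOR = 1.28  # ages 46-47, first screen
YOUNGER_SECOND_GROUP_FACTOR = 1.247  # ages 48-49
YOUNGER_FORMER_FIRST_FACTOR = 0.881  # ages 50-51, loses the prevalence peak

SENSITIVITY_KINDS = (
    "incidence+10%",
    "incidence-10%",
    "costs+10%",
    "costs+50%",
    "stage+0.02",
    "stage-0.02",
)


@dataclass(frozen=True)
class Scenario:
    """A named (inputs, policy) pair ready for the cohort engine.

    ``modelled_incidence_groups`` / ``modelled_stage_groups`` record which
    age-group indices were modelled (rather than observed) when the scenario
    was built; sensitivity variants perturb exactly these.
    """

    name: str
    inputs: ModelInputs
    policy: PolicyVector
    modelled_incidence_groups: tuple[int, ...] = ()
    modelled_stage_groups: tuple[int, ...] = ()


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative scenario transform applied to a baseline.

    Transforms, in application order:

    1. ``screen_groups`` — flip the listed group indices to S;
    2. ``stage_substitutions`` — ``(target_j, source_j, source_status)``:
       the target group's conditional stage distribution *under the new
       policy's status* becomes the baseline distribution of ``source_j``
       under ``source_status`` ('S'/'NS');
    3. ``incidence_multipliers`` — ``(j, factor)``: the incidence the new
       policy selects at ``j`` becomes the baseline policy-selected rate
       times ``factor``;
    4. ``incidence_overrides`` — ``{j: rate}`` replacements at the new
       policy's status;
    5. ``stage_shift`` — move ``stage_shift_delta`` of conditional mass from
       regional (stage 2) to localized (stage 1) for the listed groups
       (negative delta moves it the other way);
    6. ``cost_scale`` — multiply every treatment cost cell (screening cost
       untouched).
    """

    name: str = "scenario"
    screen_groups: tuple[int, ...] = ()
    stage_substitutions: tuple[tuple[int, int, str], ...] = ()
    incidence_multipliers: tuple[tuple[int, float], ...] = ()
    incidence_overrides: dict[int, float] = field(default_factory=dict)
    stage_shift_delta: float = 0.0
    stage_shift_groups: tuple[int, ...] = ()
    cost_scale: float = 1.0
    modelled_incidence_groups: tuple[int, ...] = ()
    modelled_stage_groups: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        """JSON/YAML-ready representation (inverse of :meth:`from_dict`)."""
        return {
            "name": self.name,
            "screen_groups": list(self.screen_groups),
            "stage_substitutions": [list(s) for s in self.stage_substitutions],
            "incidence_multipliers": [list(m) for m in self.incidence_multipliers],
            "incidence_overrides": {str(j): v for j, v in self.incidence_overrides.items()},
            "stage_shift_delta": self.stage_shift_delta,
            "stage_shift_groups": list(self.stage_shift_groups),
            "cost_scale": self.cost_scale,
            "modelled_incidence_groups": list(self.modelled_incidence_groups),
            "modelled_stage_groups": list(self.modelled_stage_groups),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioSpec":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown scenario-config keys: {sorted(unknown)}")
        return cls(
            name=data.get("name", "scenario"),
            screen_groups=tuple(data.get("screen_groups", ())),
            stage_substitutions=tuple(
                (int(t), int(s), str(st)) for t, s, st in data.get("stage_substitutions", ())
            ),
            incidence_multipliers=tuple(
                (int(j), float(f)) for j, f in data.get("incidence_multipliers", ())
            ),
            incidence_overrides={
                int(j): float(v) for j, v in data.get("incidence_overrides", {}).items()
            },
            stage_shift_delta=float(data.get("stage_shift_delta", 0.0)),
            stage_shift_groups=tuple(data.get("stage_shift_groups", ())),
            cost_scale=float(data.get("cost_scale", 1.0)),
            modelled_incidence_groups=tuple(data.get("modelled_incidence_groups", ())),
            modelled_stage_groups=tuple(data.get("modelled_stage_groups", ())),
        )

    def apply(self, baseline: ModelInputs, base_policy: PolicyVector) -> Scenario:
        """Build the scenario; the baseline objects are never mutated."""
        if self.cost_scale <= 0:
            raise ValidationError(f"cost_scale must be > 0, got {self.cost_scale!r}")
        grid = baseline.age_grid
        policy = base_policy.with_screened(self.screen_groups)

        q = baseline.stages.q.copy()
        iota = baseline.incidence.iota.copy()

        for target_j, source_j, source_status in self.stage_substitutions:
            if not 0 <= source_j < grid.n_groups:
                raise ValidationError(
                    f"{self.name}: stage-substitution source group {source_j} missing"
                )
            s_idx = 1 if source_status == "S" else 0
            q[target_j, policy.status_index(target_j)] = baseline.stages.q[
                source_j, s_idx
            ]

        for j, factor in self.incidence_multipliers:
            if factor <= 0:
                raise ValidationError(f"{self.name}: incidence factor must be > 0")
            iota[j, policy.status_index(j)] = (
                baseline.incidence.iota[j, base_policy.status_index(j)] * factor
            )

        for j, rate in self.incidence_overrides.items():
            iota[j, policy.status_index(j)] = rate

        if self.stage_shift_delta != 0.0:
            for j in self.stage_shift_groups:
                s = policy.status_index(j)
                q[j, s, 1] += self.stage_shift_delta
                q[j, s, 2] -= self.stage_shift_delta
                if q[j, s, 1] < 0 or q[j, s, 2] < 0:
                    raise ValidationError(
                        f"{self.name}: stage shift {self.stage_shift_delta:+g} drives a "
                        f"conditional probability negative at group {j}"
                    )

        cost_model = baseline.cost_model
        if self.cost_scale != 1.0:
            cost_model = cost_model.scale_treatment(self.cost_scale)

        inputs = baseline.replace(
            incidence=IncidenceSchedule(iota),
            stages=ConditionalStageDistribution(q),
            cost_model=cost_model,
        )
        require_valid(inputs)
        return Scenario(
            name=self.name,
            inputs=inputs,
            policy=policy,
            modelled_incidence_groups=self.modelled_incidence_groups,
            modelled_stage_groups=self.modelled_stage_groups,
        )


def _require_groups(grid: AgeGrid, ages: list[int], what: str) -> list[int]:
    try:
        return [grid.group_of_age(a) for a in ages]
    except ValidationError as err:
        raise ValidationError(f"{what}: {err}") from err


def younger_extension_spec(grid: AgeGrid) -> ScenarioSpec:
    j46, j48, j50, j52 = _require_groups(grid, [46, 48, 50, 52], "younger extension")
    modelled_inc = tuple(j for j in range(grid.n_groups) if grid.lower_age(j) + 1 <= 69)
    return ScenarioSpec(
        name="46-69 yr",
        screen_groups=(j46, j48),
        stage_substitutions=((j46, j50, "S"), (j48, j52, "S"), (j50, j52, "S")),
        incidence_multipliers=(
            (j46, YOUNGER_FIRST_SCREEN_FACTOR),
            (j48, YOUNGER_SECOND_GROUP_FACTOR),
            (j50, YOUNGER_FORMER_FIRST_FACTOR),
        ),
        modelled_incidence_groups=tuple(modelled_inc),
        modelled_stage_groups=(j46, j48, j50),
    )


def older_extension_spec(
    grid: AgeGrid, older_incidence: dict[int, float]
) -> ScenarioSpec:
    """Spec for extending screening to ages 70-73.

    ``older_incidence`` maps group index -> replacement incidence rate for
    the groups above age 69; the two newly screened groups must be covered.
    """
    j68, j70, j72 = _require_groups(grid, [68, 70, 72], "older extension")
    missing = [j for j in (j70, j72) if j not in older_incidence]
    if missing:
        raise ValidationError(
            f"older extension: incidence overrides missing for screened groups {missing}"
        )
    older = [j for j in range(grid.n_groups) if grid.lower_age(j) > 69]
    # newly screened groups copy 68-69's screened profile; above them the
    # baseline old-age profile shifts down by two groups (four years).
    subs = [(j70, j68, "S"), (j72, j68, "S")]
    for j in older:
        if j in (j70, j72):
            continue
        subs.append((j, j - 2, "NS"))
    return ScenarioSpec(
        name="50-74 yr",
        screen_groups=(j70, j72),
        stage_substitutions=tuple(subs),
        incidence_overrides=dict(older_incidence),
        modelled_incidence_groups=tuple(older),
        modelled_stage_groups=tuple(older),
    )


def _merge_specs(name: str, a: ScenarioSpec, b: ScenarioSpec) -> ScenarioSpec:
    return ScenarioSpec(
        name=name,
        screen_groups=a.screen_groups + b.screen_groups,
        stage_substitutions=a.stage_substitutions + b.stage_substitutions,
        incidence_multipliers=a.incidence_multipliers + b.incidence_multipliers,
        incidence_overrides={**a.incidence_overrides, **b.incidence_overrides},
        modelled_incidence_groups=tuple(
            sorted(set(a.modelled_incidence_groups) | set(b.modelled_incidence_groups))
        ),
        modelled_stage_groups=tuple(
            sorted(set(a.modelled_stage_groups) | set(b.modelled_stage_groups))
        ),
    )


def build_younger_extension(
    baseline: ModelInputs, base_policy: PolicyVector | None = None
) -> Scenario:
    """Extend screening down to age 46 (groups 46-47 and 48-49)."""
    base_policy = base_policy or PolicyVector.screening_ages(baseline.age_grid, 50, 69)
    return younger_extension_spec(baseline.age_grid).apply(baseline, base_policy)


def build_older_extension(
    baseline: ModelInputs,
    older_incidence: dict[int, float],
    base_policy: PolicyVector | None = None,
) -> Scenario:
    """Extend screening up to age 73 (groups 70-71 and 72-73)."""
    base_policy = base_policy or PolicyVector.screening_ages(baseline.age_grid, 50, 69)
    return older_extension_spec(baseline.age_grid, older_incidence).apply(
        baseline, base_policy
    )


def build_both_extension(
    baseline: ModelInputs,
    older_incidence: dict[int, float],
    base_policy: PolicyVector | None = None,
) -> Scenario:
    """Extend screening in both directions (ages 46-73 screened).

    Composition of the younger and older transforms; they touch disjoint age
    ranges, so the (fixed) younger-then-older order does not affect the
    result.
    """
    base_policy = base_policy or PolicyVector.screening_ages(baseline.age_grid, 50, 69)
    spec = _merge_specs(
        "46-74 yr",
        younger_extension_spec(baseline.age_grid),
        older_extension_spec(baseline.age_grid, older_incidence),
    )
    return spec.apply(baseline, base_policy)


def build_standard_scenarios(
    baseline: ModelInputs,
    older_incidence: dict[int, float],
    base_policy: PolicyVector | None = None,
) -> tuple[Scenario, list[Scenario]]:
    """Reference scenario plus the three extensions, in table order."""
    base_policy = base_policy or PolicyVector.screening_ages(baseline.age_grid, 50, 69)
    require_valid(baseline)
    reference = Scenario(
        name=base_policy.label(baseline.age_grid), inputs=baseline, policy=base_policy
    )
    return reference, [
        build_younger_extension(baseline, base_policy),
        build_older_extension(baseline, older_incidence, base_policy),
        build_both_extension(baseline, older_incidence, base_policy),
    ]


def apply_sensitivity(scenario: Scenario, kind: str) -> Scenario:
    """One-way perturbation of a built scenario.

    ``kind`` is one of :data:`SENSITIVITY_KINDS`.  Incidence and stage-shift
    variants touch only the scenario's modelled groups (so the reference
    scenario, which models nothing, is returned unchanged); cost variants
    rescale every treatment cell of every scenario.  +10% and -10% are
    independent scenarios, not inverses of each other.
    """
    if kind not in SENSITIVITY_KINDS:
        raise ValidationError(f"unknown sensitivity kind {kind!r}")
    name = f"{scenario.name}"
    if kind.startswith("incidence"):
        factor = 1.1 if kind == "incidence+10%" else 0.9
        spec = ScenarioSpec(
            name=name,
            incidence_multipliers=tuple(
                (j, factor) for j in scenario.modelled_incidence_groups
            ),
            modelled_incidence_groups=scenario.modelled_incidence_groups,
            modelled_stage_groups=scenario.modelled_stage_groups,
        )
    elif kind.startswith("costs"):
        scale = 1.1 if kind == "costs+10%" else 1.5
        spec = ScenarioSpec(
            name=name,
            cost_scale=scale,
            modelled_incidence_groups=scenario.modelled_incidence_groups,
            modelled_stage_groups=scenario.modelled_stage_groups,
        )
    else:
        delta = 0.02 if kind == "stage+0.02" else -0.02
        spec = ScenarioSpec(
            name=name,
            stage_shift_delta=delta,
            stage_shift_groups=scenario.modelled_stage_groups,
            modelled_incidence_groups=scenario.modelled_incidence_groups,
            modelled_stage_groups=scenario.modelled_stage_groups,
        )
    return spec.apply(scenario.inputs, scenario.policy)
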