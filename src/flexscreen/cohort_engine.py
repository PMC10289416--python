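"""Deterministic cohort dynamics, closed-form life-years and costs, ICERs.

A cohort of ``N0`` invitees (default 100 000) enters at the first age group
and is followed through biennial screening rounds.  Individuals are censored
(removed from later rounds) once they die of any cause or are diagnosed with
breast cancer; the model measures the effect of screening only.

Expected population at round ``j + 1``::

    N_{j+1} = N_j (1 - P(T_j in {0, 1}) - P(T_j >= 2, X != -1))

where ``T_j`` is the time to death regardless of state, i.e. the mixture
``P(T_j = t) = sum_k lam_{j,k}(t) mu_{j,h}(k)``.

Total expected life-years under policy ``h``::

    E T_h = sum_{j>=2} 2 N_j
          + sum_j [ lam_{j,-1}(1) mu_{j,h}(-1)
                    + sum_{k>=0} mu_{j,h}(k) E T_{j,k} ] N_j

Year accounting (reproduced verbatim, including its asymmetries): each
arrival at round ``j >= 2`` credits the two years just lived; a cancer-free
woman dying within the interval credits 1 year if ``lam_{j,-1}(1)`` fires and
0 years at ``t = 0``; a diagnosed woman credits her full expected remaining
years ``E T_{j,k}`` at diagnosis; survivors of the final round credit nothing
further.

Total expected costs::

    E C_{j,h} = N_j Csc_h(j)
              + sum_{k>=0} N_j mu_{j,h}(k) sum_t sum_d C~(j,k,t,d) pi_{j,k}(t,d)
    E C_h    = sum_j E C_{j,h}

with ``Csc_h(j)`` the unit screening cost when group ``j`` is screened, else 0.
No discounting is applied to either costs or life-years, and none is offered
as an option: outputs stay directly comparable to the undiscounted
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cost_rules import CostModel, build_cost_tensor
from .model_core import (
    ModelInputs,
    PolicyVector,
    StateDistribution,
    SurvivalLaw,
    ValidationError,
    compose_state_distribution,
    require_valid,
)

__all__ = [
    "CohortTrajectory",
    "PolicyResult",
    "ComparisonRow",
    "marginal_death_law",
    "advance_population",
    "cohort_trajectory",
    "total_life_years",
    "total_costs",
    "expected_bc_deaths",
    "evaluate_policy",
    "compare_policies",
]

_NEG_TOL = 1e-12


@dataclass(frozen=True)
class CohortTrajectory:
    """Expected number of invitees per round (real-valued, non-increasing)."""

    n: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "n", np.asarray(self.n, dtype=float))

    @property
    def n_rounds(self) -> int:
        return self.n.size


@dataclass(frozen=True)
class PolicyResult:
    """Closed-form expectations for one policy on one parameter set."""

    policy: PolicyVector
    ec: float
    et: float
    bc_deaths: float
    trajectory: CohortTrajectory
    per_age_costs: np.ndarray
    screening_cost: float
    treatment_cost: float

    @property
    def cost_per_life_year(self) -> float:
        return self.ec / self.et if self.et > 0 else float("nan")


@dataclass(frozen=True)
class ComparisonRow:
    """One row of a policy-comparison table.

    ``incremental_cost`` and ``icer`` are the alternative-minus-reference
    differences (None on the reference row; ``icer`` also None when the
    life-year difference is exactly zero).
    """

    label: str
    ec: float
    et: float
    ratio: float
    incremental_cost: float | None
    icer: float | None
    bc_deaths: float


def marginal_death_law(
    mu: StateDistribution, survival: SurvivalLaw, j: int
) -> np.ndarray:
    """State-marginalized time-to-death mass ``P(T_j = t)`` at round ``j``."""
    if j >= survival.n_groups or j >= mu.n_groups:
        raise ValidationError(f"no survival/state law for group {j}")
    # lam[j] is (K+2, T); mu row is (K+2,)
    return mu.mu[j] @ survival.lam[j]


def advance_population(
    n_j: float, mu: StateDistribution, survival: SurvivalLaw, j: int
) -> float:
    """One step of the population recursion.

    Removes those dying within the interval (any state, ``T_j`` in {0, 1})
    and those surviving to the next round but diagnosed at round ``j``.
    """
    if n_j < 0:
        raise ValidationError(f"population must be >= 0, got {n_j!r}")
    death_law = marginal_death_law(mu, survival, j)
    p_early = float(death_law[:2].sum())
    # diagnosed and surviving at least two years
    surv_ge2 = survival.lam[j, 1:, 2:].sum(axis=1)  # (K+1,)
    p_diag_surv = float(mu.diagnosed(j) @ surv_ge2)
    keep = 1.0 - p_early - p_diag_surv
    if keep < -_NEG_TOL or keep > 1.0 + _NEG_TOL:
        raise ValidationError(
            f"inconsistent survival probability {keep!r} at group {j}"
        )
    return n_j * min(max(keep, 0.0), 1.0)


def cohort_trajectory(
    inputs: ModelInputs, mu: StateDistribution
) -> CohortTrajectory:
    n = np.empty(inputs.age_grid.n_groups)
    n[0] = inputs.n0
    for j in range(inputs.age_grid.n_groups - 1):
        n[j + 1] = advance_population(n[j], mu, inputs.survival, j)
    return CohortTrajectory(n)


def _expected_years_by_state(survival: SurvivalLaw) -> np.ndarray:
    """``E T_{j,k}`` for every (j, state index); shape (J, K+2)."""
    t = np.arange(survival.n_t)
    return survival.lam @ t


def total_life_years(
    inputs: ModelInputs, policy: PolicyVector, *, validate: bool = True
) -> tuple[float, CohortTrajectory]:
    """Total expected life-years of the cohort under ``policy``."""
    if validate:
        require_valid(inputs)
    mu = compose_state_distribution(inputs.incidence, inputs.stages, policy)
    traj = cohort_trajectory(inputs, mu)
    et_jk = _expected_years_by_state(inputs.survival)  # (J, K+2)
    per_round = (
        inputs.survival.lam[:, 0, 1] * mu.mu[:, 0]  # cancer-free, one year left
        + (mu.mu[:, 1:] * et_jk[:, 1:]).sum(axis=1)  # diagnosed: full expectation
    )
    et = 2.0 * traj.n[1:].sum() + float(per_round @ traj.n)
    return et, traj


def total_costs(
    inputs: ModelInputs, policy: PolicyVector, *, validate: bool = True
) -> tuple[float, np.ndarray]:
    """Total expected costs and the per-age-group breakdown."""
    if validate:
        require_valid(inputs)
    mu = compose_state_distribution(inputs.incidence, inputs.stages, policy)
    traj = cohort_trajectory(inputs, mu)
    per_age = _per_age_costs(inputs, policy, mu, traj)
    return float(per_age.sum()), per_age


def _per_age_costs(
    inputs: ModelInputs,
    policy: PolicyVector,
    mu: StateDistribution,
    traj: CohortTrajectory,
) -> np.ndarray:
    cost_model: CostModel = inputs.cost_model
    tensor = build_cost_tensor(cost_model, inputs.age_grid, inputs.causes.pi.shape[2])
    # expected treatment+death cost per diagnosed stage: sum_t sum_d C~ pi
    per_stage = (tensor * inputs.causes.pi).sum(axis=(2, 3))  # (J, K+1)
    treat = (mu.mu[:, 1:] * per_stage).sum(axis=1)  # per invitee of round j
    screen = np.array(
        [
            cost_model.screening_unit_cost if policy.screened(j) else 0.0
            for j in range(inputs.age_grid.n_groups)
        ]
    )
    return traj.n * (screen + treat)


def expected_bc_deaths(
    inputs: ModelInputs, policy: PolicyVector, *, validate: bool = True
) -> float:
    """Expected number of breast-cancer deaths over the cohort's lifetime."""
    if validate:
        require_valid(inputs)
    mu = compose_state_distribution(inputs.incidence, inputs.stages, policy)
    traj = cohort_trajectory(inputs, mu)
    p_bc_by_stage = inputs.causes.pi[:, :, :, 0].sum(axis=2)  # (J, K+1)
    per_round = (mu.mu[:, 1:] * p_bc_by_stage).sum(axis=1)
    return float(per_round @ traj.n)


def evaluate_policy(
    inputs: ModelInputs, policy: PolicyVector, *, validate: bool = True
) -> PolicyResult:
    """All closed-form outputs for one policy in a single pass."""
    if validate:
        require_valid(inputs)
    mu = compose_state_distribution(inputs.incidence, inputs.stages, policy)
    traj = cohort_trajectory(inputs, mu)
    et_jk = _expected_years_by_state(inputs.survival)
    per_round_years = (
        inputs.survival.lam[:, 0, 1] * mu.mu[:, 0]
        + (mu.mu[:, 1:] * et_jk[:, 1:]).sum(axis=1)
    )
    et = 2.0 * traj.n[1:].sum() + float(per_round_years @ traj.n)

    per_age = _per_age_costs(inputs, policy, mu, traj)
    screen = np.array(
        [
            inputs.cost_model.screening_unit_cost if policy.screened(j) else 0.0
            for j in range(inputs.age_grid.n_groups)
        ]
    )
    screening_cost = float(screen @ traj.n)
    ec = float(per_age.sum())

    p_bc_by_stage = inputs.causes.pi[:, :, :, 0].sum(axis=2)
    bc = float(((mu.mu[:, 1:] * p_bc_by_stage).sum(axis=1)) @ traj.n)

    return PolicyResult(
        policy=policy,
        ec=ec,
        et=et,
        bc_deaths=bc,
        trajectory=traj,
        per_age_costs=per_age,
        screening_cost=screening_cost,
        treatment_cost=ec - screening_cost,
    )


def comparison_row(
    label: str, result: PolicyResult, reference: PolicyResult | None
) -> ComparisonRow:
    """Assemble one comparison-table row against an optional reference."""
    if reference is None:
        inc, icer = None, None
    else:
        inc = result.ec - reference.ec
        d_et = result.et - reference.et
        icer = inc / d_et if d_et != 0.0 else None
    return ComparisonRow(
        label=label,
        ec=result.ec,
        et=result.et,
        ratio=result.cost_per_life_year,
        incremental_cost=inc,
        icer=icer,
        bc_deaths=result.bc_deaths,
    )


def compare_policies(
    inputs: ModelInputs,
    reference: PolicyVector,
    alternatives: list[PolicyVector],
    labels: list[str] | None = None,
) -> list[ComparisonRow]:
    """Compare alternative policies to a reference on shared inputs.

    The incremental cost and the ICER are reported alternative-minus-
    reference, so a positive ICER with positive life-year gain reads as
    "euros per life-year gained by the alternative".
    """
    if any(p.n_groups != reference.n_groups for p in alternatives):
        raise ValidationError("all policies must have the same number of groups")
    require_valid(inputs)
    grid = inputs.age_grid
    if labels is None:
        labels = [p.label(grid) for p in alternatives]
    ref_result = evaluate_policy(inputs, reference, validate=False)
    rows = [comparison_row(reference.label(grid), ref_result, None)]
    for label, policy in zip(labels, alternatives):
        rows.append(
            comparison_row(label, evaluate_policy(inputs, policy, validate=False), ref_result)
        )
    return rows
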