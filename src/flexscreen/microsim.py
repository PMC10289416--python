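"""Individual-level Monte-Carlo oracle for the closed-form cohort results.

Simulates the exact stochastic process whose expectations the cohort engine
computes in closed form, and is used to validate those closed forms: for any
valid parameter set the simulated means of total life-years, total costs and
breast-cancer deaths must agree with the analytic values within Monte-Carlo
error.

Per-individual walk (mirroring the closed-form year accounting, which is the
thing being validated — not an alternative lifetime model):

1. arrive at round ``j`` (credit 2 life-years for every arrival after the
   first — the two years just lived between rounds);
2. pay the unit screening cost if the round is screened;
3. draw the state ``k`` from ``mu_{j,h}``;
4. if diagnosed (``k >= 0``): draw ``(t, d)`` from the joint law
   ``pi_{j,k}``, credit the *drawn* ``t`` years (not its expectation — that
   is what keeps the oracle independent) and the accumulated treatment cost
   for ``(t + 1, d)``, record a breast-cancer death if ``d = 1``, stop;
5. if cancer-free: draw ``t`` from ``lam_{j,-1}``; on ``t in {0, 1}`` credit
   ``t`` years and stop; otherwise continue to round ``j + 1``.  Survivors
   of the final round credit nothing further, matching the closed form's
   accounting exactly.

Draw order is fixed (per round: one state draw for every participant, then
time-to-death draws stage by stage in ascending stage order, then the
cancer-free draw), so a cohort run is reproducible from its seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cost_rules import accumulate_cost, band_of, build_cost_tensor
from .model_core import (
    ModelInputs,
    N_STAGES,
    PolicyVector,
    ValidationError,
    compose_state_distribution,
    require_valid,
)

__all__ = ["SimConfig", "SimResult", "simulate_individual", "simulate_cohort"]


@dataclass(frozen=True)
class SimConfig:
    """One Monte-Carlo run: inputs, policy, cohort size and seed."""

    inputs: ModelInputs
    policy: PolicyVector
    n_individuals: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be >= 1")


@dataclass(frozen=True)
class SimResult:
    """Simulated totals scaled to the cohort size N0, with standard errors.

    ``et``, ``ec`` and ``bc_deaths`` are ``N0 * mean(per-individual value)``
    and are directly comparable to the closed-form outputs; ``*_se`` are the
    matching Monte-Carlo standard errors on the same scale.
    """

    et: float
    ec: float
    bc_deaths: float
    et_se: float
    ec_se: float
    bc_deaths_se: float
    n_individuals: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "et": self.et,
            "ec": self.ec,
            "bc_deaths": self.bc_deaths,
            "et_se": self.et_se,
            "ec_se": self.ec_se,
            "bc_deaths_se": self.bc_deaths_se,
            "n_individuals": self.n_individuals,
            "seed": self.seed,
        }


def _draw_categorical(rng: np.random.Generator, pmf: np.ndarray, size: int) -> np.ndarray:
    cdf = np.cumsum(pmf)
    u = rng.random(size)
    return np.minimum(np.searchsorted(cdf, u, side="right"), pmf.size - 1)


def simulate_individual(
    rng: np.random.Generator, inputs: ModelInputs, policy: PolicyVector
) -> tuple[float, float, bool]:
    """One woman's walk through the rounds: (life_years, cost, died_of_bc)."""
    grid = inputs.age_grid
    mu = compose_state_distribution(inputs.incidence, inputs.stages, policy)
    sc = inputs.cost_model.screening_unit_cost
    years, cost = 0.0, 0.0
    for j in range(grid.n_groups):
        if j > 0:
            years += 2.0
        if policy.screened(j):
            cost += sc
        k = int(_draw_categorical(rng, mu.mu[j], 1)[0]) - 1  # back to -1..K
        if k >= 0:
            joint = inputs.causes.mass(j, k).ravel()
            draw = int(_draw_categorical(rng, joint, 1)[0])
            t, d_idx = divmod(draw, 2)
            years += t
            cost += accumulate_cost(
                inputs.cost_model, t + 1, d_idx + 1, band_of(grid.lower_age(j)), k
            )
            return years, cost, d_idx == 0
        t = int(_draw_categorical(rng, inputs.survival.mass(j, -1), 1)[0])
        if t <= 1:
            years += t
            return years, cost, False
    return years, cost, False


def simulate_cohort(config: SimConfig) -> SimResult:
    """Vectorized cohort simulation; totals scaled to ``inputs.n0``."""
    inputs, policy = config.inputs, config.policy
    require_valid(inputs)
    grid = inputs.age_grid
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals

    mu = compose_state_distribution(inputs.incidence, inputs.stages, policy)
    tensor = build_cost_tensor(
        inputs.cost_model, grid, inputs.causes.pi.shape[2]
    )  # (J, K+1, T, 2)
    sc = inputs.cost_model.screening_unit_cost

    years = np.zeros(n)
    cost = np.zeros(n)
    bc_death = np.zeros(n, dtype=bool)
    active = np.arange(n)

    for j in range(grid.n_groups):
        if active.size == 0:
            break
        if j > 0:
            years[active] += 2.0
        if policy.screened(j):
            cost[active] += sc

        state = _draw_categorical(rng, mu.mu[j], active.size)  # 0..K+1; 0 = no cancer
        for k in range(N_STAGES):  # ascending stage order, fixed draw sequence
            sel = active[state == k + 1]
            if sel.size == 0:
                continue
            joint = inputs.causes.pi[j, k].ravel()  # (T*2,) in (t, d) order
            draw = _draw_categorical(rng, joint, sel.size)
            t, d_idx = np.divmod(draw, 2)
            years[sel] += t
            cost[sel] += tensor[j, k, t, d_idx]
            bc_death[sel] = d_idx == 0

        healthy = active[state == 0]
        if healthy.size:
            t = _draw_categorical(rng, inputs.survival.mass(j, -1), healthy.size)
            dies_now = t <= 1
            years[healthy[dies_now]] += t[dies_now]
            active = healthy[~dies_now]
        else:
            active = healthy

    scale = inputs.n0
    sqrt_n = np.sqrt(n)

    def _se(x: np.ndarray) -> float:
        return float(scale * np.std(x, ddof=1) / sqrt_n) if n > 1 else float("nan")

    return SimResult(
        et=float(scale * years.mean()),
        ec=float(scale * cost.mean()),
        bc_deaths=float(scale * bc_death.mean()),
        et_se=_se(years),
        ec_se=_se(cost),
        bc_deaths_se=_se(bc_death.astype(float)),
        n_individuals=n,
        seed=config.seed,
    )
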