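"""Synthetic parameter sets with the statistical shape of the Finnish inputs.

The registry estimates behind the published Finnish analysis (incidence under
screening/no-screening, stage-conditional survival, cause-of-death split) are
not public, so this module generates complete, valid parameter sets that
reproduce their *structure*:

* incidence rising with age, a prevalence peak at the first screened group,
  and a detection deficit just after screening stops;
* conditional stage distributions enriched in localized and in-situ disease
  under screening;
* stage-specific excess mortality on top of a Gompertz background life table,
  decaying to zero by 18 years after diagnosis (beyond which patients die as
  the general female population);
* a stage-graded breast-cancer vs other-cause death split.

Everything produced here is synthetic — magnitudes are field-plausible
choices, not registry estimates — except the treatment-cost tables and the
overall stage-distribution vector, which are published values shipped via
:func:`reference_costs`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cost_rules import CostModel, load_default_cost_model
from .model_core import (
    AgeGrid,
    CauseJointLaw,
    ConditionalStageDistribution,
    IncidenceSchedule,
    ModelInputs,
    N_STAGES,
    SurvivalLaw,
    ValidationError,
    require_valid,
)

__all__ = [
    "GeneratorConfig",
    "OVERALL_STAGE_DISTRIBUTION",
    "generate_inputs",
    "reference_costs",
    "toy_inputs",
    "sweden_like_overrides",
]

#: Published overall stage distribution of the Finnish screening-era cases
#: (Unknown, Localized, Regional, Distant/adjacent, In situ).  Shipped as
#: printed — the entries sum to 0.9995, not 1 — and used only as a reference
#: constant, never as a probability-simplex input.
OVERALL_STAGE_DISTRIBUTION = np.array([0.096, 0.522, 0.254, 0.0085, 0.119])


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic generator; defaults emulate the Finnish setting.

    Incidence values are two-year diagnosis probabilities per invitee.  The
    unscreened age curve is ``base_incidence * (1 + incidence_saturation *
    (1 - exp(-j / incidence_scale_groups)))`` — about 0.5% per two years in
    the late 40s saturating near 1.3% at high ages, the magnitude of Nordic
    female breast-cancer incidence.  ``screen_start_age``/``screen_stop_age``
    describe the *ongoing* program the data reflect: the prevalence bump
    multiplies detection at the program's first screened group
    (+28% by default, the first-screen effect) and the post-screening deficit
    thins the unscreened rates of the two groups just above the stop age.
    ``excess_hazard_by_stage`` is the added annual death hazard right after
    diagnosis, decaying linearly to zero over
    ``excess_mortality_decay_years`` (18 years: past that, survivors die as
    the general population).  ``bc_death_share_by_stage`` is the probability
    that a death ``t`` years after diagnosis is coded to breast cancer,
    damped by the same linear decay.
    """

    seed: int = 0
    n_groups: int = 27
    start_age: int = 46
    horizon_age: int = 100
    n0: float = 100_000.0
    base_incidence: float = 0.005
    incidence_saturation: float = 1.6
    incidence_scale_groups: float = 8.0
    screen_detection_boost: float = 0.12
    first_screen_bump: float = 0.28
    screen_start_age: int = 50
    screen_stop_age: int = 69
    post_screen_deficit: float = 0.15
    screen_effect: float = 0.12
    excess_mortality_decay_years: int = 18
    excess_hazard_by_stage: tuple[float, ...] = (0.05, 0.015, 0.07, 0.30, 0.004)
    bc_death_share_by_stage: tuple[float, ...] = (0.35, 0.15, 0.45, 0.85, 0.03)
    gompertz_level: float = 3.3e-4
    gompertz_rate: float = 0.095
    background_life_table: np.ndarray | None = None
    jitter: float = 0.08

    def violations(self) -> list[str]:
        out = []
        for name in ("base_incidence", "post_screen_deficit", "screen_effect"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                out.append(f"{name} must be in [0, 1], got {v!r}")
        for name in ("excess_hazard_by_stage", "bc_death_share_by_stage"):
            vals = getattr(self, name)
            if len(vals) != N_STAGES or any(not 0 <= v <= 1 for v in vals):
                out.append(f"{name} must be {N_STAGES} probabilities in [0, 1]")
        if self.excess_mortality_decay_years > self.horizon_age - self.start_age:
            out.append("excess_mortality_decay_years exceeds the maximal survival support")
        if self.background_life_table is not None:
            lt = np.asarray(self.background_life_table, dtype=float)
            if lt.size != self.horizon_age - self.start_age:
                out.append(
                    f"background_life_table must cover ages {self.start_age}.."
                    f"{self.horizon_age - 1} ({self.horizon_age - self.start_age} entries)"
                )
            elif ((lt < 0) | (lt > 1)).any():
                out.append("background_life_table entries must be in [0, 1]")
        return out


def _life_table(config: GeneratorConfig) -> np.ndarray:
    """Annual death probability for ages start..horizon-1; certain at 99."""
    n = config.horizon_age - config.start_age
    if config.background_life_table is not None:
        q = np.asarray(config.background_life_table, dtype=float).copy()
    else:
        ages = np.arange(n)
        q = np.minimum(0.95, config.gompertz_level * np.exp(config.gompertz_rate * ages))
    q[-1] = 1.0  # nobody survives past the horizon
    return q


def _survival_from_hazard(hazard: np.ndarray, n_t: int) -> np.ndarray:
    """Death-time mass from an annual hazard whose last entry is 1."""
    m = hazard.size
    lam = np.zeros(n_t)
    surv = 1.0
    for t in range(m):
        lam[t] = surv * hazard[t]
        surv *= 1.0 - hazard[t]
    lam[m - 1] += 1.0 - lam.sum()  # absorb float round-off into the last year
    return lam


def generate_inputs(config: GeneratorConfig = GeneratorConfig()) -> ModelInputs:
    """Generate a complete, validated parameter set from ``config``.

    Deterministic in the seed: the same config always yields the same
    inputs.
    """
    problems = config.violations()
    if problems:
        raise ValidationError(problems)
    rng = np.random.default_rng(config.seed)
    grid = AgeGrid(config.n_groups, config.start_age, config.horizon_age)
    n_t = grid.n_t
    j_idx = np.arange(grid.n_groups)

    # --- incidence --------------------------------------------------------
    curve = config.base_incidence * (
        1.0
        + config.incidence_saturation
        * (1.0 - np.exp(-j_idx / config.incidence_scale_groups))
    )
    curve = curve * np.exp(config.jitter * rng.standard_normal(grid.n_groups))
    curve = np.clip(curve, 1e-6, 0.5)

    iota = np.empty((grid.n_groups, 2))
    iota[:, 0] = curve
    iota[:, 1] = curve * (1.0 + config.screen_detection_boost)
    first_screened = [
        j for j in range(grid.n_groups) if grid.lower_age(j) == config.screen_start_age
    ]
    for j in first_screened:
        iota[j, 1] *= 1.0 + config.first_screen_bump
    post = [
        j
        for j in range(grid.n_groups)
        if grid.lower_age(j) > config.screen_stop_age
    ][:2]
    for j in post:  # detection deficit right after the program stops
        iota[j, 0] *= 1.0 - config.post_screen_deficit
    iota = np.clip(iota, 0.0, 0.9)

    # --- conditional stage distributions ----------------------------------
    base = np.array([0.10, 0.42, 0.33, 0.04, 0.11])
    q_ns = np.tile(base, (grid.n_groups, 1))
    trend = np.minimum(0.002 * j_idx, 0.05)  # older: slightly more advanced
    q_ns[:, 1] -= trend
    q_ns[:, 2] += trend
    q_ns *= np.exp(0.05 * config.jitter / 0.08 * rng.standard_normal(q_ns.shape))
    q_ns /= q_ns.sum(axis=1, keepdims=True)

    q_s = q_ns.copy()
    if config.screen_effect > 0:
        # mass moved out of regional/distant into localized/in-situ, capped so
        # nothing goes negative
        shift = np.minimum(
            config.screen_effect,
            np.minimum(q_ns[:, 2] / 0.9, q_ns[:, 3] / 0.1) * 0.999,
        )
        q_s[:, 1] += 0.8 * shift
        q_s[:, 4] += 0.2 * shift
        q_s[:, 2] -= 0.9 * shift
        q_s[:, 3] -= 0.1 * shift
    q = np.stack([q_ns, q_s], axis=1)  # (J, 2, K+1)

    # --- survival and cause of death --------------------------------------
    life = _life_table(config)
    excess = np.array(config.excess_hazard_by_stage) * np.exp(
        0.2 * rng.standard_normal(N_STAGES)
    )
    excess = np.clip(excess, 0.0, 0.95)
    bc_share = np.array(config.bc_death_share_by_stage)
    decay_t = np.maximum(
        0.0, 1.0 - np.arange(n_t) / config.excess_mortality_decay_years
    )

    lam = np.zeros((grid.n_groups, N_STAGES + 1, n_t))
    pi = np.zeros((grid.n_groups, N_STAGES, n_t, 2))
    for j in range(grid.n_groups):
        lo = grid.lower_age(j) - config.start_age
        bg = life[lo:]  # annual hazard from this group's age on; ends at 1
        lam[j, 0] = _survival_from_hazard(bg, n_t)
        for k in range(N_STAGES):
            hz = 1.0 - (1.0 - bg) * (1.0 - excess[k] * decay_t[: bg.size])
            hz[-1] = 1.0
            lam[j, k + 1] = _survival_from_hazard(hz, n_t)
            w = bc_share[k] * decay_t
            pi[j, k, :, 0] = lam[j, k + 1] * w
            pi[j, k, :, 1] = lam[j, k + 1] - pi[j, k, :, 0]

    inputs = ModelInputs(
        age_grid=grid,
        incidence=IncidenceSchedule(iota),
        stages=ConditionalStageDistribution(q),
        survival=SurvivalLaw(lam),
        causes=CauseJointLaw(pi),
        cost_model=load_default_cost_model(),
        n0=config.n0,
    )
    return require_valid(inputs)


def reference_costs() -> tuple[CostModel, np.ndarray]:
    """The packaged published cost tables and overall stage distribution.

    Returns the full 7-band x 5-stage phase cost tables with the 30 euro
    screening unit cost, plus the published overall stage-distribution vector
    (see :data:`OVERALL_STAGE_DISTRIBUTION`; shipped as printed, sum 0.9995).
    All other model ingredients must come from :func:`generate_inputs` or
    user-supplied parameter files.
    """
    return load_default_cost_model(), OVERALL_STAGE_DISTRIBUTION.copy()


def toy_inputs(seed: int = 7, n_groups: int = 3) -> ModelInputs:
    """Tiny fixture (3 age groups by default) for examples and fast tests."""
    return generate_inputs(GeneratorConfig(seed=seed, n_groups=n_groups))


def sweden_like_overrides(
    inputs: ModelInputs,
    stop_age: int = 69,
    taper_per_group: float = 0.35,
) -> dict[int, float]:
    """Synthetic stand-in incidence pattern for screening extended past 69.

    Emulates the qualitative shape observed where screening runs to age 74:
    the newly screened groups keep the screened (boosted) detection rate and
    the excess tapers away linearly over the following groups.  This is a
    constructed pattern for exercising the older-extension scenario, not an
    estimate of any country's incidence curve.
    """
    grid = inputs.age_grid
    older = [j for j in range(grid.n_groups) if grid.lower_age(j) > stop_age]
    if not older:
        raise ValidationError(f"grid has no groups above age {stop_age}")
    overrides: dict[int, float] = {}
    last_screened = older[1] if len(older) > 1 else older[0]
    for j in older:
        frac = max(0.0, 1.0 - taper_per_group * max(0, j - last_screened))
        ns, s = inputs.incidence.iota[j]
        overrides[j] = float(ns + (s - ns) * frac)
    return overrides
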