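"""Shared fixtures: hand-built degenerate inputs and seeded synthetic ones."""

from __future__ import annotations

import numpy as np
import pytest

from flexscreen import (
    AgeGrid,
    CauseJointLaw,
    ConditionalStageDistribution,
    GeneratorConfig,
    IncidenceSchedule,
    ModelInputs,
    SurvivalLaw,
    generate_inputs,
    load_default_cost_model,
)
from flexscreen.model_core import N_STAGES

DEFAULT_Q = (0.1, 0.5, 0.25, 0.01, 0.14)


def point_mass(t: int, n_t: int) -> np.ndarray:
    row = np.zeros(n_t)
    row[t] = 1.0
    return row


def build_inputs(
    n_groups: int = 1,
    *,
    iota=0.0,
    q=DEFAULT_Q,
    lam=None,
    pi=None,
    default_t: int = 10,
    bc_share: float = 0.0,
    n0: float = 100_000.0,
    screening_unit_cost: float = 30.0,
) -> ModelInputs:
    """Small, fully explicit inputs for exact-value tests.

    Defaults: every state (including cancer-free) is a point mass at
    ``default_t`` years, deaths are all other-cause, incidence ``iota`` is
    shared by both screening statuses, and the conditional stage law ``q``
    is shared by every group.  ``lam``/``pi`` override whole arrays.
    """
    grid = AgeGrid(n_groups)
    n_t = grid.n_t
    iota_arr = np.broadcast_to(np.asarray(iota, dtype=float), (n_groups, 2)).copy()
    q_arr = np.broadcast_to(np.asarray(q, dtype=float), (n_groups, 2, N_STAGES)).copy()
    if lam is None:
        lam = np.zeros((n_groups, N_STAGES + 1, n_t))
        lam[:, :, default_t] = 1.0
    if pi is None:
        pi = np.zeros((n_groups, N_STAGES, n_t, 2))
        pi[:, :, :, 0] = lam[:, 1:, :] * bc_share
        pi[:, :, :, 1] = lam[:, 1:, :] * (1.0 - bc_share)
    return ModelInputs(
        age_grid=grid,
        incidence=IncidenceSchedule(iota_arr),
        stages=ConditionalStageDistribution(q_arr),
        survival=SurvivalLaw(np.asarray(lam, dtype=float)),
        causes=CauseJointLaw(np.asarray(pi, dtype=float)),
        cost_model=load_default_cost_model(screening_unit_cost=screening_unit_cost),
        n0=n0,
    )


@pytest.fixture(scope="session")
def toy():
    """Three-group synthetic fixture."""
    return generate_inputs(GeneratorConfig(seed=7, n_groups=3))


@pytest.fixture(scope="session")
def small6():
    """Six-group synthetic fixture used across engine tests."""
    return generate_inputs(GeneratorConfig(seed=11, n_groups=6))


@pytest.fixture(scope="session")
def finnish_like():
    """Full 27-group synthetic baseline."""
    return generate_inputs(GeneratorConfig(seed=3))
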