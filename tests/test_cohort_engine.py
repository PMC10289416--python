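"""Cohort dynamics, closed-form life-years/costs and policy comparison."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flexscreen import (
    GeneratorConfig,
    PolicyVector,
    advance_population,
    compare_policies,
    compose_state_distribution,
    evaluate_policy,
    expected_bc_deaths,
    generate_inputs,
    marginal_death_law,
    total_costs,
    total_life_years,
)
from flexscreen.cohort_engine import cohort_trajectory
from flexscreen.model_core import CauseJointLaw, SurvivalLaw

from conftest import build_inputs, point_mass


def _mu(inputs, policy):
    return compose_state_distribution(inputs.incidence, inputs.stages, policy)


class TestMarginalDeathLaw:
    def test_single_component_returns_background_law(self):
        inputs = build_inputs(iota=0.0, default_t=10)
        policy = PolicyVector.no_screening(1)
        law = marginal_death_law(_mu(inputs, policy), inputs.survival, 0)
        assert law == pytest.approx(inputs.survival.mass(0, -1))

    def test_two_point_mass_mixture(self):
        inputs = build_inputs(iota=1.0, q=(0.0, 1.0, 0.0, 0.0, 0.0))
        lam = inputs.survival.lam.copy()
        lam[0, 0] = point_mass(1, lam.shape[2])
        lam[0, 2] = point_mass(3, lam.shape[2])
        pi = np.zeros_like(inputs.causes.pi)
        pi[0, :, :, 1] = lam[0, 1:]
        inputs = inputs.replace(survival=SurvivalLaw(lam), causes=CauseJointLaw(pi))
        # half no-cancer (mass at t=1), half localized (mass at t=3)
        iota = inputs.incidence.iota.copy()
        iota[:] = 0.5
        inputs = inputs.replace(incidence=type(inputs.incidence)(iota))
        law = marginal_death_law(
            _mu(inputs, PolicyVector.no_screening(1)), inputs.survival, 0
        )
        assert law[1] == pytest.approx(0.5)
        assert law[3] == pytest.approx(0.5)
        assert law.sum() == pytest.approx(1.0)

    def test_matches_brute_force_mixture(self, small6):
        policy = PolicyVector.screening_ages(small6.age_grid, 50, 69)
        mu = _mu(small6, policy)
        for j in range(small6.age_grid.n_groups):
            brute = sum(
                mu.mu[j, ki] * small6.survival.lam[j, ki]
                for ki in range(small6.survival.lam.shape[1])
            )
            assert marginal_death_law(mu, small6.survival, j) == pytest.approx(brute)


class TestAdvancePopulation:
    def test_nobody_leaves_without_cancer_or_death(self):
        inputs = build_inputs(n_groups=2, iota=0.0, default_t=10)
        mu = _mu(inputs, PolicyVector.no_screening(2))
        assert advance_population(1000.0, mu, inputs.survival, 0) == pytest.approx(1000.0)

    def test_early_deaths_thin_the_cohort(self):
        inputs = build_inputs(n_groups=2, iota=0.0)
        lam = inputs.survival.lam.copy()
        lam[0, 0] = 0.9 * point_mass(10, lam.shape[2]) + 0.1 * point_mass(1, lam.shape[2])
        inputs = inputs.replace(survival=SurvivalLaw(lam))
        mu = _mu(inputs, PolicyVector.no_screening(2))
        assert advance_population(1.0, mu, inputs.survival, 0) == pytest.approx(0.9)

    def test_diagnosis_censors_survivors(self):
        inputs = build_inputs(n_groups=2, iota=0.01, default_t=10)
        mu = _mu(inputs, PolicyVector.no_screening(2))
        assert advance_population(1.0, mu, inputs.survival, 0) == pytest.approx(0.99)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_trajectory_non_increasing(self, seed):
        inputs = generate_inputs(GeneratorConfig(seed=seed, n_groups=6))
        mu = _mu(inputs, PolicyVector.screening_ages(inputs.age_grid, 50, 69))
        traj = cohort_trajectory(inputs, mu)
        assert (np.diff(traj.n) <= 1e-9).all()
        assert (traj.n >= 0).all()
        assert traj.n[0] == inputs.n0


class TestTotalLifeYears:
    def test_single_round_everyone_lives_one_year(self):
        inputs = build_inputs(n_groups=1, iota=0.0)
        lam = np.zeros_like(inputs.survival.lam)
        lam[:, :, 1] = 1.0
        inputs = inputs.replace(survival=SurvivalLaw(lam))
        pi = np.zeros_like(inputs.causes.pi)
        pi[:, :, 1, 1] = 1.0
        inputs = inputs.replace(causes=CauseJointLaw(pi))
        et, traj = total_life_years(inputs, PolicyVector.no_screening(1))
        assert et == pytest.approx(inputs.n0)
        assert traj.n == pytest.approx([inputs.n0])

    def test_two_rounds_only_interval_years(self):
        # everyone cancer-free, survives >= 2 years, never exactly 1:
        # only the two-year arrival credits contribute
        inputs = build_inputs(n_groups=2, iota=0.0, default_t=10)
        et, traj = total_life_years(inputs, PolicyVector.no_screening(2))
        assert traj.n[1] == pytest.approx(inputs.n0)
        assert et == pytest.approx(2 * inputs.n0)

    def test_crude_upper_bound(self, small6):
        et, _ = total_life_years(
            small6, PolicyVector.screening_ages(small6.age_grid, 50, 69)
        )
        grid = small6.age_grid
        assert 0 < et <= small6.n0 * (2 * grid.n_groups + grid.n_t)

    def test_monotone_under_survival_improvement(self, small6):
        """First-order dominance shifts of the diagnosed-stage laws (and the
        non-terminal cancer-free laws) never decrease total life-years."""
        policy = PolicyVector.screening_ages(small6.age_grid, 50, 69)
        base_et, _ = total_life_years(small6, policy)
        lam = small6.survival.lam.copy()
        pi = small6.causes.pi.copy()
        grid = small6.age_grid
        for j in range(grid.n_groups):
            t_cap = grid.t_max(j)
            for ki in range(lam.shape[1]):
                if ki == 0 and j == grid.n_groups - 1:
                    continue  # terminal-round healthy law: accounting asymmetry
                t = int(np.argmax(lam[j, ki, :t_cap]))
                move = 0.5 * lam[j, ki, t]
                lam[j, ki, t] -= move
                lam[j, ki, t + 1] += move
                if ki > 0:
                    frac = pi[j, ki - 1, t] / pi[j, ki - 1, t].sum()
                    pi[j, ki - 1, t] -= move * frac
                    pi[j, ki - 1, t + 1] += move * frac
        improved = small6.replace(survival=SurvivalLaw(lam), causes=CauseJointLaw(pi))
        better_et, _ = total_life_years(improved, policy)
        assert better_et >= base_et - 1e-6


class TestTotalCosts:
    def test_no_screening_no_cancer_is_free(self):
        inputs = build_inputs(n_groups=3, iota=0.0, default_t=10)
        ec, per_age = total_costs(inputs, PolicyVector.no_screening(3))
        assert ec == 0.0
        assert per_age == pytest.approx(np.zeros(3))

    def test_screening_only_cost(self):
        inputs = build_inputs(n_groups=3, iota=0.0, default_t=10)
        ec, per_age = total_costs(inputs, PolicyVector.all_screening(3))
        # nobody dies or is diagnosed: N_j = N0 at every round
        assert per_age == pytest.approx(np.full(3, 30.0 * inputs.n0))
        assert ec == pytest.approx(3 * 30.0 * inputs.n0)

    def test_per_age_costs_sum_to_total(self, small6):
        policy = PolicyVector.screening_ages(small6.age_grid, 50, 69)
        ec, per_age = total_costs(small6, policy)
        assert ec == pytest.approx(per_age.sum())

    @pytest.mark.parametrize("alpha", [1.1, 1.5])
    def test_treatment_scaling_linearity(self, small6, alpha):
        policy = PolicyVector.screening_ages(small6.age_grid, 50, 69)
        base = evaluate_policy(small6, policy)
        scaled = evaluate_policy(
            small6.replace(cost_model=small6.cost_model.scale_treatment(alpha)), policy
        )
        expected = base.screening_cost + alpha * base.treatment_cost
        assert scaled.ec == pytest.approx(expected, rel=1e-9)
        assert scaled.screening_cost == pytest.approx(base.screening_cost, rel=1e-12)


class TestExpectedBcDeaths:
    def test_no_bc_mortality_means_zero(self):
        inputs = build_inputs(iota=0.05, bc_share=0.0)
        assert expected_bc_deaths(inputs, PolicyVector.no_screening(1)) == 0.0

    def test_all_diagnosed_die_of_bc(self):
        inputs = build_inputs(iota=0.01, bc_share=1.0)
        deaths = expected_bc_deaths(inputs, PolicyVector.no_screening(1))
        assert deaths == pytest.approx(0.01 * inputs.n0)


class TestComparePolicies:
    def test_identical_alternative_has_zero_increment(self, small6):
        policy = PolicyVector.screening_ages(small6.age_grid, 50, 69)
        rows = compare_policies(small6, policy, [policy])
        assert rows[0].incremental_cost is None and rows[0].icer is None
        assert rows[1].incremental_cost == 0.0
        assert rows[1].icer is None  # zero life-year difference

    def test_cost_only_change_when_added_group_has_no_cancer(self):
        inputs = build_inputs(n_groups=3, iota=0.0, default_t=10)
        ref = PolicyVector.no_screening(3)
        alt = PolicyVector(("S", "NS", "NS"))
        rows = compare_policies(inputs, ref, [alt])
        assert rows[1].incremental_cost == pytest.approx(30.0 * inputs.n0)
        assert rows[1].icer is None  # life-years unchanged exactly

    def test_icer_matches_hand_computation(self, small6):
        ref = PolicyVector.screening_ages(small6.age_grid, 50, 69)
        alt = PolicyVector.all_screening(small6.age_grid.n_groups)
        rows = compare_policies(small6, ref, [alt])
        r_ref = evaluate_policy(small6, ref)
        r_alt = evaluate_policy(small6, alt)
        assert rows[1].incremental_cost == pytest.approx(r_alt.ec - r_ref.ec)
        assert rows[1].icer == pytest.approx(
            (r_alt.ec - r_ref.ec) / (r_alt.et - r_ref.et)
        )
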