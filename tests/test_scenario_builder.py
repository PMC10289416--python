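"""Policy-extension scenarios and one-way sensitivity transforms."""

from __future__ import annotations

import copy

import pytest

from flexscreen import (
    PolicyVector,
    ValidationError,
    apply_sensitivity,
    build_both_extension,
    build_older_extension,
    build_standard_scenarios,
    build_younger_extension,
    evaluate_policy,
    expected_remaining_years,
    sweden_like_overrides,
    validate_inputs,
)
from flexscreen.scenario_builder import ScenarioSpec


@pytest.fixture(scope="module")
def baseline(finnish_like):
    return finnish_like


@pytest.fixture(scope="module")
def current(baseline):
    return PolicyVector.screening_ages(baseline.age_grid, 50, 69)


@pytest.fixture(scope="module")
def overrides(baseline):
    return sweden_like_overrides(baseline)


class TestYoungerExtension:
    def test_policy_flips_and_incidence_multipliers(self, baseline, current):
        scen = build_younger_extension(baseline, current)
        grid = baseline.age_grid
        j46, j48, j50 = (grid.group_of_age(a) for a in (46, 48, 50))
        assert scen.policy.screened(j46) and scen.policy.screened(j48)
        # multipliers act on the baseline policy-selected rate
        base_ns = baseline.incidence.iota[:, 0]
        base_s = baseline.incidence.iota[:, 1]
        new_s = scen.inputs.incidence.iota[:, 1]
        assert new_s[j46] / base_ns[j46] == pytest.approx(1.28)
        assert new_s[j48] / base_ns[j48] == pytest.approx(1.247)
        assert new_s[j50] / base_s[j50] == pytest.approx(0.881)

    def test_stage_substitutions_copy_exactly(self, baseline, current):
        scen = build_younger_extension(baseline, current)
        grid = baseline.age_grid
        j46, j48, j50, j52 = (grid.group_of_age(a) for a in (46, 48, 50, 52))
        q_new, q_old = scen.inputs.stages.q, baseline.stages.q
        S = 1
        assert (q_new[j46, S] == q_old[j50, S]).all()
        assert (q_new[j48, S] == q_old[j52, S]).all()
        assert (q_new[j50, S] == q_old[j52, S]).all()

    def test_builder_is_pure(self, baseline, current):
        before = copy.deepcopy(
            (baseline.incidence.iota, baseline.stages.q, baseline.survival.lam)
        )
        build_younger_extension(baseline, current)
        assert (baseline.incidence.iota == before[0]).all()
        assert (baseline.stages.q == before[1]).all()
        assert (baseline.survival.lam == before[2]).all()

    def test_output_validates(self, baseline, current):
        scen = build_younger_extension(baseline, current)
        assert validate_inputs(scen.inputs) == []


class TestOlderExtension:
    def test_newly_screened_copy_68_69_profile(self, baseline, current, overrides):
        scen = build_older_extension(baseline, overrides, current)
        grid = baseline.age_grid
        j68, j70, j72 = (grid.group_of_age(a) for a in (68, 70, 72))
        S = 1
        assert (scen.inputs.stages.q[j70, S] == baseline.stages.q[j68, S]).all()
        assert (scen.inputs.stages.q[j72, S] == baseline.stages.q[j68, S]).all()
        assert scen.policy.screened(j70) and scen.policy.screened(j72)
        assert not scen.policy.screened(grid.group_of_age(74))

    def test_two_group_downward_shift_above_73(self, baseline, current, overrides):
        scen = build_older_extension(baseline, overrides, current)
        grid = baseline.age_grid
        NS = 0
        j74 = grid.group_of_age(74)
        assert (
            scen.inputs.stages.q[j74, NS]
            == baseline.stages.q[grid.group_of_age(70), NS]
        ).all()
        j80 = grid.group_of_age(80)
        assert (
            scen.inputs.stages.q[j80, NS]
            == baseline.stages.q[grid.group_of_age(76), NS]
        ).all()

    def test_overrides_replace_incidence(self, baseline, current, overrides):
        scen = build_older_extension(baseline, overrides, current)
        for j, rate in overrides.items():
            s = scen.policy.status_index(j)
            assert scen.inputs.incidence.iota[j, s] == pytest.approx(rate)

    def test_missing_screened_override_rejected(self, baseline, current, overrides):
        partial = {j: v for j, v in overrides.items() if j != min(overrides)}
        with pytest.raises(ValidationError, match="missing"):
            build_older_extension(baseline, partial, current)

    def test_identity_spec_returns_baseline_unchanged(self, baseline, current):
        scen = ScenarioSpec(name="identity").apply(baseline, current)
        assert (scen.inputs.incidence.iota == baseline.incidence.iota).all()
        assert (scen.inputs.stages.q == baseline.stages.q).all()
        assert scen.policy == current


class TestBothExtension:
    def test_policy_spans_46_to_73(self, baseline, current, overrides):
        scen = build_both_extension(baseline, overrides, current)
        grid = baseline.age_grid
        for j in range(grid.n_groups):
            expected = 46 <= grid.lower_age(j) <= 72
            assert scen.policy.screened(j) == expected

    def test_composition_matches_components(self, baseline, current, overrides):
        both = build_both_extension(baseline, overrides, current)
        younger = build_younger_extension(baseline, current)
        older = build_older_extension(baseline, overrides, current)
        grid = baseline.age_grid
        j46 = grid.group_of_age(46)
        assert both.inputs.incidence.iota[j46, 1] == pytest.approx(
            younger.inputs.incidence.iota[j46, 1]
        )
        # the transforms touch disjoint age ranges: older-side arrays agree
        older_groups = [j for j in range(grid.n_groups) if grid.lower_age(j) > 69]
        for j in older_groups:
            assert (
                both.inputs.stages.q[j] == older.inputs.stages.q[j]
            ).all()

    def test_identity_transformations_reproduce_baseline_result(
        self, baseline, current
    ):
        scen = ScenarioSpec(name="identity").apply(baseline, current)
        base_res = evaluate_policy(baseline, current)
        scen_res = evaluate_policy(scen.inputs, scen.policy)
        assert scen_res.ec == base_res.ec
        assert scen_res.et == base_res.et
        assert scen_res.bc_deaths == base_res.bc_deaths


class TestSensitivity:
    def test_cost_scaling_leaves_screening_cost(self, baseline, current, overrides):
        scen = build_younger_extension(baseline, current)
        varied = apply_sensitivity(scen, "costs+50%")
        assert varied.inputs.cost_model.c1 == pytest.approx(1.5 * scen.inputs.cost_model.c1)
        assert (
            varied.inputs.cost_model.screening_unit_cost
            == scen.inputs.cost_model.screening_unit_cost
        )

    def test_incidence_up_and_down_are_not_inverses(self, baseline, current):
        scen = build_younger_extension(baseline, current)
        up = apply_sensitivity(scen, "incidence+10%")
        down = apply_sensitivity(up, "incidence-10%")
        j = scen.modelled_incidence_groups[0]
        s = scen.policy.status_index(j)
        assert down.inputs.incidence.iota[j, s] != pytest.approx(
            scen.inputs.incidence.iota[j, s], rel=1e-12
        )

    def test_stage_shift_moves_exactly_002(self, baseline, current):
        scen = build_younger_extension(baseline, current)
        varied = apply_sensitivity(scen, "stage+0.02")
        j46 = baseline.age_grid.group_of_age(46)
        s = scen.policy.status_index(j46)
        q0, q1 = scen.inputs.stages.q[j46, s], varied.inputs.stages.q[j46, s]
        assert q1[1] - q0[1] == pytest.approx(0.02)
        assert q1[2] - q0[2] == pytest.approx(-0.02)
        assert q1[[0, 3, 4]] == pytest.approx(q0[[0, 3, 4]])

    def test_reference_unaffected_by_incidence_and_stage_variants(
        self, baseline, current, overrides
    ):
        reference, _ = build_standard_scenarios(baseline, overrides, current)
        for kind in ("incidence+10%", "incidence-10%", "stage+0.02", "stage-0.02"):
            varied = apply_sensitivity(reference, kind)
            assert (varied.inputs.incidence.iota == baseline.incidence.iota).all()
            assert (varied.inputs.stages.q == baseline.stages.q).all()

    def test_positive_shift_beats_negative_when_localized_survives_longer(
        self, baseline, current
    ):
        scen = build_younger_extension(baseline, current)
        for j in scen.modelled_stage_groups:
            et1 = expected_remaining_years(scen.inputs.survival.mass(j, 1))
            et2 = expected_remaining_years(scen.inputs.survival.mass(j, 2))
            assert et1 >= et2  # precondition of the directional claim
        up = apply_sensitivity(scen, "stage+0.02")
        down = apply_sensitivity(scen, "stage-0.02")
        et_up = evaluate_policy(up.inputs, up.policy).et
        et_down = evaluate_policy(down.inputs, down.policy).et
        assert et_up >= et_down

    def test_unknown_kind_rejected(self, baseline, current):
        scen = build_younger_extension(baseline, current)
        with pytest.raises(ValidationError):
            apply_sensitivity(scen, "costs+200%")
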