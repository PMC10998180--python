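"""Unit and property tests for the habit dynamics and the point equation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from habitpoints import (
    HabitState,
    ModelParams,
    RoundingMode,
    compute_points,
    init_strength,
    long_term_benefit,
    n_to_goal,
    point_curve,
    update_strength,
    value_to_go,
)
from habitpoints.model import apply_report, point_curve_csv

strengths = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestUpdateStrength:
    @pytest.mark.parametrize(
        "s, action, expected",
        [
            (1.0, 1, 1.0),  # full strength is a fixed point of enactment
            (0.0, 0, 0.0),  # zero strength is a fixed point of failure
            (2 / 7, 1, 2 / 7 + 0.1 * 5 / 7),
            (2 / 7, 0, 0.9 * 2 / 7),
        ],
    )
    def test_update_rule(self, s, action, expected, params):
        assert update_strength(s, action, params) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("bad", [-0.1, 1.1, float("nan"), float("inf")])
    def test_rejects_out_of_domain_strength(self, bad, params):
        with pytest.raises(ValueError):
            update_strength(bad, 1, params)

    def test_rejects_invalid_action(self, params):
        with pytest.raises(ValueError):
            update_strength(0.5, 2, params)

    @settings(derandomize=True, max_examples=200)
    @given(s=strengths, action=st.sampled_from([0, 1]))
    def test_stays_in_unit_interval(self, s, action):
        params = ModelParams()
        assert 0.0 <= update_strength(s, action, params) <= 1.0

    def test_repeated_enactment_increases_to_one(self, params):
        s = 0.3
        prev = s
        for _ in range(200):
            s = update_strength(s, 1, params)
            assert s > prev
            prev = s
        assert s == pytest.approx(1.0, abs=1e-8)

    def test_repeated_failure_decreases_to_zero(self, params):
        s = 0.7
        prev = s
        for _ in range(200):
            s = update_strength(s, 0, params)
            assert s < prev
            prev = s
        assert s == pytest.approx(0.0, abs=1e-8)


class TestNToGoal:
    @pytest.mark.parametrize(
        "s, expected",
        [
            (0.9, 0),  # already at threshold
            (0.09, 21),
            (0.081, 22),  # one failure at 0.09 adds a required enactment
            (0.10, 21),
            (0.08, 22),
            (0.0, 22),
        ],
    )
    def test_required_enactment_counts(self, s, expected, params):
        assert n_to_goal(s, params) == expected

    def test_failure_leaves_count_unchanged_at_008_and_010(self, params):
        # the nonmonotonic jump happens at 0.09 but not at its neighbors
        for s, n in [(0.08, 22), (0.10, 21)]:
            assert n_to_goal(s, params) == n
            assert n_to_goal(update_strength(s, 0, params), params) == n

    def test_above_threshold_is_zero(self, params):
        assert n_to_goal(0.95, params) == 0


class TestValueToGo:
    def test_at_threshold_equals_goal_reward(self):
        params = ModelParams(goal_reward=5.0)
        assert value_to_go(0.9, params) == 5.0

    @pytest.mark.parametrize(
        "s, expected",
        [(2 / 7, -6.17797), (0.9 * 2 / 7, -6.52543)],
    )
    def test_remaining_effort_cost(self, s, expected, params):
        assert value_to_go(s, params) == pytest.approx(expected, abs=1e-4)

    def test_goal_reward_shifts_value_by_constant(self, params):
        shifted = params.with_(goal_reward=10.0)
        for s in np.linspace(0, 1, 17):
            assert value_to_go(s, shifted) - value_to_go(s, params) == pytest.approx(10.0, abs=1e-12)


class TestLongTermBenefit:
    def test_failure_at_zero_strength_is_neutral(self, params):
        assert long_term_benefit(0.0, 0, params) == 0.0

    def test_enactment_benefit_closed_form(self, params):
        assert long_term_benefit(0.25, 1, params) == pytest.approx(0.75, abs=1e-12)

    def test_failure_benefit_value_difference(self, params):
        assert long_term_benefit(2 / 7, 0, params) == pytest.approx(-0.34747, abs=1e-4)

    def test_enactment_identity_on_dense_grid(self, params):
        # f(s, 1) = 1 - s wherever the habit is not yet built
        grid = np.linspace(0, params.theta, 10_000, endpoint=False)
        errs = [abs(long_term_benefit(s, 1, params) - (1 - s)) for s in grid]
        assert max(errs) < 1e-9

    def test_failure_benefit_nonpositive(self, params):
        for s in np.linspace(0, 1, 101):
            assert long_term_benefit(s, 0, params) <= 0.0


class TestComputePoints:
    def test_worked_example(self, params):
        s = 2 / 7
        assert compute_points(s, 1, params) == 9
        assert compute_points(s, 0, params) == -4

    def test_nearest_rounding_changes_the_penalty(self, params):
        # M * f(2/7, 0) = -4.52: truncation gives -4, nearest gives -5
        nearest = params.with_(rounding_mode=RoundingMode.NEAREST_HALF_AWAY)
        assert compute_points(2 / 7, 0, nearest) == -5
        assert compute_points(2 / 7, 1, nearest) == 9

    def test_endpoints(self, params):
        assert compute_points(0.0, 1, params) == params.max_points
        assert compute_points(params.theta, 1, params) == 0

    @settings(derandomize=True, max_examples=200)
    @given(s=strengths, action=st.sampled_from([0, 1]), r_goal=st.sampled_from([0.0, 1.0, 10.0]))
    def test_goal_reward_invariance(self, s, action, r_goal):
        base = ModelParams()
        assert compute_points(s, action, base.with_(goal_reward=r_goal)) == compute_points(s, action, base)

    def test_sign_and_bound(self, params):
        for s in np.linspace(0, params.theta, 91):
            p1, p0 = compute_points(s, 1, params), compute_points(s, 0, params)
            assert p1 >= 0 >= p0
            assert abs(p1) <= params.max_points and abs(p0) <= params.max_points

    def test_enact_points_non_increasing(self, params):
        pts = [compute_points(s, 1, params) for s in np.linspace(0, 1, 301)]
        assert all(a >= b for a, b in zip(pts, pts[1:]))


class TestApplyReport:
    def test_points_use_pre_update_strength(self, params):
        state = HabitState(strength=2 / 7, score=40, day=0)
        new_state, feedback = apply_report(state, 1, params)
        assert feedback.points_delta == 9  # from 2/7, not from the updated strength
        assert new_state.score == 49
        assert new_state.strength == pytest.approx(2 / 7 + 0.1 * 5 / 7)

    def test_sign_invariants(self, params):
        for action in (0, 1):
            state = HabitState(strength=0.5, score=0, day=3)
            _, fb = apply_report(state, action, params)
            if action == 1:
                assert fb.points_delta >= 0 and fb.strength_after >= fb.strength_before
            else:
                assert fb.points_delta <= 0 and fb.strength_after <= fb.strength_before


class TestInitStrength:
    @pytest.mark.parametrize("days, expected", [(0, 0.0), (2, 2 / 7), (7, 1.0)])
    def test_fraction_of_week(self, days, expected):
        assert init_strength(days) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [-1, 8, 2.5, "2"])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            init_strength(bad)


class TestPointCurve:
    def test_coarse_grid_endpoints(self, params):
        rows = point_curve(params, grid_step=0.1)
        assert rows[0] == (0.0, 13, 0)
        assert rows[-1][0] == pytest.approx(params.theta)
        assert rows[-1][1] == 0

    def test_sign_convention_on_every_row(self, params):
        for s, p1, p0 in point_curve(params, grid_step=0.01):
            assert p1 >= 0 >= p0

    def test_penalty_slope_close_to_minus_m(self, params):
        # the penalty curve is approximately linear with slope -M
        rows = point_curve(params, grid_step=0.01)
        s = np.array([r[0] for r in rows])
        p0 = np.array([r[2] for r in rows])
        slope = np.polyfit(s, p0, 1)[0]
        assert abs(slope - (-params.max_points)) / params.max_points < 0.15

    def test_csv_header_and_precision(self, params):
        lines = point_curve_csv(params, grid_step=0.1).splitlines()
        assert lines[0] == "strength,points_enact,points_fail"
        assert lines[1].startswith("0.000000,")


class TestModelParams:
    @pytest.mark.parametrize(
        "kwargs",
        [{"alpha": 0.0}, {"alpha": 1.0}, {"theta": 1.5}, {"max_points": 0}, {"eps": 0.0}, {"goal_reward": -1}],
    )
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_dict_round_trip(self, params):
        assert ModelParams.from_dict(params.to_dict()) == params

    def test_rejects_unknown_keys(self):
        with pytest.raises(ValueError):
            ModelParams.from_dict({"alpha": 0.1, "beta": 2})
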