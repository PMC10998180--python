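"""Habit-formation MDP and the optimized point equation.

The model tracks a single habit strength :math:`s \\in [0, 1]`.  Enacting
the behavior (action 1) moves the strength to :math:`s + \\alpha(1 - s)`;
failing to enact (action 0) decays it to :math:`s(1 - \\alpha)`.  The habit
counts as cultivated once the strength reaches a threshold :math:`\\theta`,
at which point a goal reward :math:`r_\\mathrm{goal}` accrues.  Enacting
costs effort :math:`-(1 - s)`; skipping is free.

For a user who follows through with building the habit, the value-to-go
from strength :math:`s` is the goal reward minus the remaining effort
costs along the always-enact trajectory:

.. math::

    V^*(s) = r_\\mathrm{goal} - \\sum_{k=0}^{n(s;\\theta)-1} (1 - s_k)
           = r_\\mathrm{goal} - \\frac{(1-s)\\,(1-(1-\\alpha)^n)}{\\alpha},

where :math:`n(s;\\theta)` is the number of enactments needed to reach
:math:`\\theta`.  The long-term benefit of action :math:`a` at strength
:math:`s` is the value difference :math:`f(s,a) = V^*(s') - V^*(s)` with
:math:`s'` the post-action strength; for enactment this collapses to the
closed form :math:`f(s,1) = 1 - s`.  Points are the integerization of
:math:`M \\cdot f(s, a)` (the point equation), so the maximum award is
:math:`M` at strength 0 and awards shrink to 0 at the threshold.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence


class RoundingMode(str, enum.Enum):
    """How ``M * f(s, a)`` is turned into an integer point value.

    ``TRUNCATE_TOWARD_ZERO`` drops the fractional part (the default; it
    reproduces the deployed chatbot's printed +9/-4 worked example), while
    ``NEAREST_HALF_AWAY`` rounds to the nearest integer with ties away
    from zero.
    """

    TRUNCATE_TOWARD_ZERO = "truncate_toward_zero"
    NEAREST_HALF_AWAY = "nearest_half_away"


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the habit-formation MDP and the point equation.

    Parameters
    ----------
    alpha : float
        Habit learning rate in (0, 1): the fraction of the remaining gap
        to full strength closed by one enactment, and the proportional
        decay applied on failure.
    theta : float
        Target habit strength in (0, 1) at which the habit counts as
        cultivated.
    max_points : int
        Maximal point value ``M`` (the award at strength 0).
    goal_reward : float
        Reward ``r_goal`` attained on reaching the threshold.  It shifts
        every value-to-go by a constant and therefore cancels from every
        point computation; it is retained for value reporting.
    rounding_mode : RoundingMode
        Integerization mode for the point equation.
    eps : float
        Comparison tolerance used when testing whether the strength has
        reached the threshold.
    """

    alpha: float = 0.1
    theta: float = 0.9
    max_points: int = 13
    goal_reward: float = 0.0
    rounding_mode: RoundingMode = RoundingMode.TRUNCATE_TOWARD_ZERO
    eps: float = 1e-12

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.theta < 1.0:
            raise ValueError(f"theta must lie in (0, 1), got {self.theta}")
        if not (isinstance(self.max_points, int) and self.max_points >= 1):
            raise ValueError(f"max_points must be a positive integer, got {self.max_points}")
        if self.goal_reward < 0.0:
            raise ValueError(f"goal_reward must be nonnegative, got {self.goal_reward}")
        if self.eps <= 0.0:
            raise ValueError(f"eps must be positive, got {self.eps}")
        # tolerate the string form so YAML round-trips cleanly
        object.__setattr__(self, "rounding_mode", RoundingMode(self.rounding_mode))

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "theta": self.theta,
            "max_points": self.max_points,
            "goal_reward": self.goal_reward,
            "rounding_mode": self.rounding_mode.value,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown ModelParams keys: {sorted(unknown)}")
        return cls(**data)

    def with_(self, **changes) -> "ModelParams":
        return replace(self, **changes)


@dataclass
class HabitState:
    """Current habit strength, cumulative score, and day index."""

    strength: float = 0.0
    score: int = 0
    day: int = 0

    def __post_init__(self) -> None:
        _check_strength(self.strength)
        if self.day < 0:
            raise ValueError(f"day must be nonnegative, got {self.day}")


@dataclass(frozen=True)
class FeedbackResult:
    """Outcome of one enactment report: action, points, strength change."""

    action: int
    points_delta: int
    strength_before: float
    strength_after: float
    benefit: float


def _check_strength(strength: float) -> None:
    if not (isinstance(strength, (int, float)) and math.isfinite(strength)):
        raise ValueError(f"strength must be a finite number, got {strength!r}")
    if not 0.0 <= strength <= 1.0:
        raise ValueError(f"strength must lie in [0, 1], got {strength}")


def _check_action(action: int) -> None:
    if action not in (0, 1):
        raise ValueError(f"action must be 0 or 1, got {action!r}")


def update_strength(strength: float, action: int, params: ModelParams) -> float:
    """Apply one habit update.

    Enactment: ``s + alpha * (1 - s)``.  Failure: ``s * (1 - alpha)``.
    Both maps keep the strength in [0, 1]; 1 is a fixed point of
    enactment and 0 a fixed point of failure.
    """
    _check_strength(strength)
    _check_action(action)
    if action == 1:
        return strength + params.alpha * (1.0 - strength)
    return strength * (1.0 - params.alpha)


def at_goal(strength: float, params: ModelParams) -> bool:
    """Whether the strength has reached the threshold (within ``eps``)."""
    return strength >= params.theta - params.eps


def n_to_goal(strength: float, params: ModelParams) -> int:
    """Number of enactments needed to raise ``strength`` to the threshold.

    Uses the closed form
    ``ceil( ln((1 - theta) / (1 - s)) / ln(1 - alpha) )`` — the gap
    ``1 - s`` shrinks geometrically by ``1 - alpha`` per enactment — with
    an exact local adjustment so the result always matches the iterative
    definition (the count of updates until ``s >= theta - eps``) even when
    floating point lands on a ceiling boundary.
    """
    _check_strength(strength)
    if at_goal(strength, params):
        return 0
    gap = 1.0 - strength
    target_gap = 1.0 - params.theta
    n = math.ceil(math.log(target_gap / gap) / math.log(1.0 - params.alpha))
    n = max(n, 0)
    # s_k >= theta - eps  <=>  gap * (1-alpha)^k <= target_gap + eps
    decay = 1.0 - params.alpha
    while n > 0 and gap * decay ** (n - 1) <= target_gap + params.eps:
        n -= 1
    while gap * decay ** n > target_gap + params.eps:
        n += 1
    return n


def value_to_go(strength: float, params: ModelParams) -> float:
    """Value of holding strength ``s`` and following through to the goal.

    ``r_goal - (1 - s)(1 - (1 - alpha)^n) / alpha`` with
    ``n = n_to_goal(s)``; equals ``r_goal`` at or above the threshold.
    """
    _check_strength(strength)
    n = n_to_goal(strength, params)
    if n == 0:
        return params.goal_reward
    gap = 1.0 - strength
    return params.goal_reward - gap * (1.0 - (1.0 - params.alpha) ** n) / params.alpha


def long_term_benefit(strength: float, action: int, params: ModelParams) -> float:
    """Long-term benefit ``f(s, a)``: the value-to-go difference of acting.

    For enactment below the threshold this equals ``1 - s`` analytically;
    the failure benefit is nonpositive and varies nonmonotonically with
    strength because the required enactment count jumps in unit steps.
    """
    _check_strength(strength)
    _check_action(action)
    after = update_strength(strength, action, params)
    return value_to_go(after, params) - value_to_go(strength, params)


def _integerize(x: float, mode: RoundingMode) -> int:
    if mode is RoundingMode.TRUNCATE_TOWARD_ZERO:
        return math.trunc(x)
    # round half away from zero (banker's rounding would bias small awards)
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def compute_points(strength: float, action: int, params: ModelParams) -> int:
    """Integer points for reporting ``action`` at ``strength``.

    The point equation: ``M * f(s, a)`` integerized under the configured
    rounding mode.  Awards are nonnegative, deductions nonpositive, and
    magnitudes never exceed ``M`` on [0, theta].
    """
    benefit = long_term_benefit(strength, action, params)
    return _integerize(params.max_points * benefit, params.rounding_mode)


def apply_report(state: HabitState, action: int, params: ModelParams) -> tuple[HabitState, FeedbackResult]:
    """Process one report: compute points on the pre-update strength, then update.

    Points are a function of the state in which the action was taken, so
    the strength update happens after the point computation.
    """
    _check_action(action)
    points = compute_points(state.strength, action, params)
    benefit = long_term_benefit(state.strength, action, params)
    after = update_strength(state.strength, action, params)
    new_state = HabitState(strength=after, score=state.score + points, day=state.day + 1)
    return new_state, FeedbackResult(
        action=action,
        points_delta=points,
        strength_before=state.strength,
        strength_after=after,
        benefit=benefit,
    )


def init_strength(days_enacted_last_week: int) -> float:
    """Initial habit strength from the days enacted in the previous week: ``n/7``."""
    if not (isinstance(days_enacted_last_week, int) and not isinstance(days_enacted_last_week, bool)):
        raise ValueError(f"days_enacted_last_week must be an integer, got {days_enacted_last_week!r}")
    if not 0 <= days_enacted_last_week <= 7:
        raise ValueError(f"days_enacted_last_week must lie in 0..7, got {days_enacted_last_week}")
    return days_enacted_last_week / 7.0


def point_curve(params: ModelParams, grid_step: float = 0.01) -> list[tuple[float, int, int]]:
    """Tabulate (strength, points for enacting, points for failing) on [0, theta].

    The enact column decreases from ``M`` at strength 0 to 0 at the
    threshold; the fail column is nonpositive and roughly linear with
    slope ``-M``.
    """
    if not 0.0 < grid_step < 1.0:
        raise ValueError(f"grid_step must lie in (0, 1), got {grid_step}")
    rows: list[tuple[float, int, int]] = []
    n_steps = int(round(params.theta / grid_step))
    grid = [min(k * grid_step, params.theta) for k in range(n_steps + 1)]
    if grid[-1] < params.theta:
        grid.append(params.theta)
    for s in grid:
        rows.append((s, compute_points(s, 1, params), compute_points(s, 0, params)))
    return rows


def point_curve_csv(params: ModelParams, grid_step: float = 0.01) -> str:
    """Render :func:`point_curve` as CSV with a fixed header."""
    lines = ["strength,points_enact,points_fail"]
    for s, p1, p0 in point_curve(params, grid_step):
        lines.append(f"{s:.6f},{p1},{p0}")
    return "\n".join(lines) + "\n"


def enactment_trajectory(strength: float, params: ModelParams, steps: int) -> Iterator[float]:
    """Yield the strength path under repeated enactment (``steps`` updates)."""
    _check_strength(strength)
    s = strength
    for _ in range(steps):
        s = update_strength(s, 1, params)
        yield s
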