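"""Myopic-agent simulation and a three-arm synthetic trial.

The study design this emulates compares three arms of a 21-day
intervention: ``optimized`` (reminders, text feedback, and engine-computed
points), ``text_feedback`` (reminders and positive/neutral text, no
points), and ``baseline`` (a bare neutral acknowledgment).  Simulated
users are purely myopic: each day they weigh the immediate effort of
enacting, ``effort_weight * (1 - s)``, against the immediate utility of
the feedback their arm delivers, and choose by a logistic rule.  Under
the optimized arm the point values are exactly the engine's long-term
benefits, so a sufficiently point-sensitive myopic agent enacts at every
strength below the threshold — the incentive-alignment property the point
equation is designed for.

The agent utility parameterization (point utility ``v``, effort weight,
logistic sharpness ``beta``, text bonuses) is this package's own
construction for testing and fixture generation; it is not a fitted model
of any human population, and no quantitative match to field data is
implied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from habitpoints.model import (
    ModelParams,
    _check_strength,
    compute_points,
    update_strength,
)
from habitpoints.session import CONDITIONS, EventRecord

__all__ = [
    "AgentProfile",
    "TrialConfig",
    "myopic_choice",
    "simulate_participant",
    "simulate_trial",
    "summarize_trial",
]


@dataclass(frozen=True)
class AgentProfile:
    """Behavioral parameters of a simulated myopic user.

    ``point_utility`` (v) converts points into utility; ``effort_weight``
    scales the immediate enactment cost ``1 - s``; ``choice_sharpness``
    (beta) is the logistic slope, with ``math.inf`` meaning strict argmax
    (ties break toward skipping); the two text bonuses are the
    point-equivalent utilities of a positive and a neutral feedback
    message in the text arm.  Defaults are chosen so that all three arms
    produce interior enactment rates.
    """

    point_utility: float = 0.15
    effort_weight: float = 1.0
    choice_sharpness: float = 3.0
    text_bonus_positive: float = 1.0
    text_bonus_neutral: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("point_utility", "effort_weight", "choice_sharpness"):
            v = getattr(self, name)
            if v < 0 or math.isnan(v):
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if math.isinf(self.point_utility) or math.isinf(self.effort_weight):
            raise ValueError("point_utility and effort_weight must be finite")


@dataclass(frozen=True)
class TrialConfig:
    """Configuration of a synthetic multi-arm trial.

    Initial strengths are drawn as ``k/7`` with ``k`` uniform on
    ``initial_days_range`` (inclusive), mirroring the onboarding
    question's support of days-enacted-last-week.
    """

    arms: tuple[str, ...] = ("optimized", "text_feedback", "baseline")
    n_per_arm: int = 50
    days: int = 21
    params: ModelParams = field(default_factory=ModelParams)
    agent: AgentProfile = field(default_factory=AgentProfile)
    initial_days_range: tuple[int, int] = (0, 4)

    def __post_init__(self) -> None:
        for arm in self.arms:
            if arm not in CONDITIONS:
                raise ValueError(f"unknown arm {arm!r}; expected one of {sorted(CONDITIONS)}")
        if self.n_per_arm < 1:
            raise ValueError(f"n_per_arm must be >= 1, got {self.n_per_arm}")
        if self.days < 1:
            raise ValueError(f"days must be >= 1, got {self.days}")
        lo, hi = self.initial_days_range
        if not (0 <= lo <= hi <= 7):
            raise ValueError(f"initial_days_range must satisfy 0 <= lo <= hi <= 7, got {self.initial_days_range}")

    def to_dict(self) -> dict:
        return {
            "arms": list(self.arms),
            "n_per_arm": self.n_per_arm,
            "days": self.days,
            "params": self.params.to_dict(),
            "agent": {
                "point_utility": self.agent.point_utility,
                "effort_weight": self.agent.effort_weight,
                "choice_sharpness": self.agent.choice_sharpness,
                "text_bonus_positive": self.agent.text_bonus_positive,
                "text_bonus_neutral": self.agent.text_bonus_neutral,
                "seed": self.agent.seed,
            },
            "initial_days_range": list(self.initial_days_range),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TrialConfig":
        data = dict(data)
        if "arms" in data:
            data["arms"] = tuple(data["arms"])
        if "params" in data and isinstance(data["params"], dict):
            data["params"] = ModelParams.from_dict(data["params"])
        if "agent" in data and isinstance(data["agent"], dict):
            data["agent"] = AgentProfile(**data["agent"])
        if "initial_days_range" in data:
            data["initial_days_range"] = tuple(data["initial_days_range"])
        return cls(**data)


def _feedback_points(strength: float, action: int, condition: str, profile: AgentProfile, params: ModelParams) -> float:
    """Point-equivalent immediate feedback utility delivered by an arm."""
    if condition == "optimized":
        return float(compute_points(strength, action, params))
    if condition == "text_feedback":
        return profile.text_bonus_positive if action == 1 else profile.text_bonus_neutral
    return 0.0  # baseline: neutral "OK", no reward signal


def myopic_choice(
    strength: float,
    condition: str,
    profile: AgentProfile,
    params: ModelParams,
    rng: np.random.Generator,
) -> int:
    """One myopic decision: enact (1) or skip (0).

    Immediate utilities are
    ``U1 = -effort_weight * (1 - s) + v * feedback(s, 1)`` and
    ``U0 = v * feedback(s, 0)``; the agent enacts with probability
    ``logistic(beta * (U1 - U0))``.  With infinite sharpness the choice is
    the argmax, ties breaking toward skipping (the costless default).
    """
    _check_strength(strength)
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    v = profile.point_utility
    u1 = -profile.effort_weight * (1.0 - strength) + v * _feedback_points(strength, 1, condition, profile, params)
    u0 = v * _feedback_points(strength, 0, condition, profile, params)
    delta = u1 - u0
    if math.isinf(profile.choice_sharpness):
        return 1 if delta > 0 else 0
    p_enact = 1.0 / (1.0 + math.exp(-profile.choice_sharpness * delta))
    return int(rng.random() < p_enact)


def simulate_participant(
    condition: str,
    profile: AgentProfile,
    params: ModelParams,
    days: int,
    initial_strength: float,
    seed: int | Sequence[int],
    participant: str = "sim",
) -> list[EventRecord]:
    """Simulate one participant's daily report cycle.

    Each day: the agent chooses, points are computed on the pre-update
    strength (engine points in the optimized arm, zero otherwise), the
    strength is updated, and one report record is appended.  The log has
    exactly ``days`` records and is bit-for-bit reproducible under the
    same seed.
    """
    if days < 1:
        raise ValueError(f"days must be >= 1, got {days}")
    _check_strength(initial_strength)
    rng = np.random.default_rng(seed)
    s = initial_strength
    score = 0
    log: list[EventRecord] = []
    for day in range(1, days + 1):
        action = myopic_choice(s, condition, profile, params, rng)
        points = compute_points(s, action, params) if condition == "optimized" else 0
        after = update_strength(s, action, params)
        score += points
        log.append(
            EventRecord(
                participant=participant,
                day=day,
                event_kind="report",
                enacted=action,
                points_delta=points,
                strength_before=s,
                strength_after=after,
                score_after=score,
            )
        )
        s = after
    return log


def simulate_trial(config: TrialConfig, seed: int = 0) -> pd.DataFrame:
    """Run a full synthetic trial; one row per participant.

    Columns: ``participant, arm, days, enactments, final_strength,
    final_score``.  Each participant gets a deterministic substream
    derived from the root seed and their global index, so enlarging
    ``n_per_arm`` never reshuffles earlier participants.
    """
    rows = []
    idx = 0
    for arm in config.arms:
        for j in range(config.n_per_arm):
            # one stream per participant: initial-strength draw, then choices
            init_rng = np.random.default_rng((seed, idx, 0))
            lo, hi = config.initial_days_range
            k = int(init_rng.integers(lo, hi + 1))
            s0 = k / 7.0
            log = simulate_participant(
                arm,
                config.agent,
                config.params,
                config.days,
                s0,
                seed=(seed, idx, 1),
                participant=f"p{idx:04d}",
            )
            rows.append(
                {
                    "participant": f"p{idx:04d}",
                    "arm": arm,
                    "days": config.days,
                    "enactments": sum(r.enacted for r in log),
                    "final_strength": log[-1].strength_after,
                    "final_score": log[-1].score_after,
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def summarize_trial(table: pd.DataFrame) -> pd.DataFrame:
    """Per-arm mean and SD of enactment counts, final strength and score."""
    return (
        table.groupby("arm", sort=False)
        .agg(
            n=("participant", "count"),
            mean_enactments=("enactments", "mean"),
            sd_enactments=("enactments", "std"),
            mean_final_strength=("final_strength", "mean"),
            mean_final_score=("final_score", "mean"),
        )
        .reset_index()
    )
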