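"""Brute-force verification of the engine's closed forms.

Everything here re-derives the model quantities by direct iteration of the
habit update rules — never by calling the closed-form code paths in
:mod:`habitpoints.model` — so the two routes stay independent.  The
duplication is deliberate: these functions are the oracle against which
the geometric-series value formula, the logarithmic enactment count, and
the ``f(s, 1) = 1 - s`` identity are checked, both in the test suite and
via the ``verify`` CLI command.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from habitpoints.model import ModelParams, _check_strength

#: Iteration cap; alpha near 0 makes the enactment count diverge, and a
#: run that hits the cap signals a parameter pathology, not a slow case.
MAX_ITERATIONS = 10**6


class OracleIterationError(RuntimeError):
    """Raised when brute-force iteration exceeds the hard cap."""


@dataclass
class OracleReport:
    """Result of a closed-form vs brute-force comparison run."""

    grid_size: int
    max_abs_error: float
    mismatch_count: int
    details: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.mismatch_count == 0

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(
            {
                "grid_size": self.grid_size,
                "max_abs_error": self.max_abs_error,
                "mismatch_count": self.mismatch_count,
                "details": [list(d) for d in self.details],
            },
            indent=indent,
        )


def brute_force_n(strength: float, params: ModelParams) -> int:
    """Count enactment updates until the strength reaches the threshold.

    Pure iteration of ``s <- s + alpha * (1 - s)``; no logarithms.
    """
    _check_strength(strength)
    s = strength
    n = 0
    while s < params.theta - params.eps:
        if n >= MAX_ITERATIONS:
            raise OracleIterationError(
                f"no threshold crossing within {MAX_ITERATIONS} iterations "
                f"(alpha={params.alpha}, theta={params.theta})"
            )
        s = s + params.alpha * (1.0 - s)
        n += 1
    return n


def brute_force_value(strength: float, params: ModelParams) -> float:
    """Sum per-step effort costs along the always-enact trajectory.

    Accumulates ``-(1 - s_k)`` step by step and adds the goal reward at
    the threshold crossing; no geometric-series closed form is used.
    """
    _check_strength(strength)
    s = strength
    total = 0.0
    n = 0
    while s < params.theta - params.eps:
        if n >= MAX_ITERATIONS:
            raise OracleIterationError(
                f"no threshold crossing within {MAX_ITERATIONS} iterations "
                f"(alpha={params.alpha}, theta={params.theta})"
            )
        total -= 1.0 - s
        s = s + params.alpha * (1.0 - s)
        n += 1
    return params.goal_reward + total


def verify_closed_forms(
    params: ModelParams,
    grid_size: int = 1000,
    tolerance: float = 1e-9,
    max_details: int = 20,
) -> OracleReport:
    """Compare the engine's closed forms against brute force on a uniform grid.

    Checks three things at each grid strength in [0, 1]:

    1. the closed-form enactment count equals the iterative count exactly;
    2. the geometric-series value-to-go matches the summed trajectory
       costs within ``tolerance``;
    3. below the threshold, the value-difference benefit of enacting
       equals ``1 - s`` within ``tolerance``.

    Mismatches are collected into the report (up to ``max_details``
    entries); nothing is raised.
    """
    from habitpoints.model import long_term_benefit, n_to_goal, value_to_go

    if grid_size < 2:
        raise ValueError(f"grid_size must be at least 2, got {grid_size}")

    max_abs_error = 0.0
    mismatches: list[tuple[float, float, float]] = []
    for i in range(grid_size):
        s = i / (grid_size - 1)
        n_closed = n_to_goal(s, params)
        n_brute = brute_force_n(s, params)
        if n_closed != n_brute:
            mismatches.append((s, float(n_brute), float(n_closed)))
        v_closed = value_to_go(s, params)
        v_brute = brute_force_value(s, params)
        err = abs(v_closed - v_brute)
        max_abs_error = max(max_abs_error, err)
        if err > tolerance:
            mismatches.append((s, v_brute, v_closed))
        if s < params.theta - params.eps:
            f1 = long_term_benefit(s, 1, params)
            err = abs(f1 - (1.0 - s))
            max_abs_error = max(max_abs_error, err)
            if err > tolerance:
                mismatches.append((s, 1.0 - s, f1))
    return OracleReport(
        grid_size=grid_size,
        max_abs_error=max_abs_error,
        mismatch_count=len(mismatches),
        details=mismatches[:max_details],
    )
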