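# Methods

## Model and assumptions

The engine models a single habit as a one-dimensional MDP. The state is
the habit strength *s* ∈ [0, 1]; there is one decision per day (enact,
*a* = 1, or skip, *a* = 0). Enactment applies *s* ← *s* + α(1 − *s*),
failure applies *s* ← *s*(1 − α); both maps keep the state in [0, 1],
with 1 a fixed point of enactment and 0 of failure. Enacting costs
−(1 − *s*) (effort falls as the habit strengthens), skipping is free,
and a goal reward *r*<sub>goal</sub> accrues once *s* reaches the target
threshold θ.

The value-to-go assumes the user follows through with building the habit
— it values only the always-enact trajectory, not an optimal policy over
an arbitrary state space. Because the gap 1 − *s* shrinks geometrically
by 1 − α per enactment, both the remaining enactment count and the
remaining cost have closed forms:

- *n*(*s*; θ) = ⌈ ln((1 − θ)/(1 − *s*)) / ln(1 − α) ⌉ for *s* < θ, else 0;
- *V*\*(*s*) = *r*<sub>goal</sub> − (1 − *s*)(1 − (1 − α)<sup>n</sup>)/α.

The points for an action are *M* · *f*(*s*, *a*) integerized, where
*f*(*s*, *a*) is the value-to-go difference the action induces. This is a
potential-based shaping term: it adds a telescoping sequence to the
reward stream, so maximizing immediate points is consistent with
maximizing long-run value, which is exactly why a myopic user is steered
correctly. For enactment *f*(*s*, 1) = 1 − *s* exactly (the enact
trajectory from *s* passes through the post-enactment state, so the
counts differ by one and the values by the single-step cost). The failure
benefit *f*(*s*, 0) has no such smooth form: it jumps wherever the
required count *n* steps by one, e.g. a failure at *s* = 0.09 raises *n*
from 21 to 22 while at 0.08 and 0.10 the counts (22 and 21) are
unchanged. Despite those jumps, the penalty curve is well approximated by
a line of slope −*M*; on the default 0.01-step grid the least-squares
slope is within about 1.5% of −*M*, and it stays within 15% for every
grid step between 0.005 and 0.1.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| α | fraction of the remaining gap closed per enactment; decay rate on failure | 0.1 | the example application's value; a habit forms in ~22 enactments from scratch |
| θ | strength at which the habit counts as cultivated | 0.9 | example application's value |
| *M* | maximal point value (award at strength 0) | 13 | example application's value |
| *r*<sub>goal</sub> | reward at threshold crossing | 0 | cancels from every point computation (it shifts all values by a constant); kept for value reporting |
| rounding_mode | integerization of *M*·*f* | truncate toward zero | see below |
| eps | threshold-comparison tolerance | 1e-12 | guards the ceiling boundary in the closed form |

## Numerical choices

**Integerization.** The deployed system's worked example awards +9 and
deducts 4 at *s* = 2/7, but the exact scaled benefit of failing is
*M* · *f*(2/7, 0) ≈ −4.52, which nearest-rounds to −5. Truncation toward
zero reproduces both printed values (+9.29 → 9 and −4.52 → −4), so it is
the default; nearest rounding (ties away from zero) is available as an
option. This derivation is reproduced by the oracle-backed tests.

**Threshold semantics.** "Reaching" θ is read as *s* ≥ θ − eps with
eps = 1e-12. At the documented inputs, strict and non-strict comparison
yield identical integers. The engine keeps running after the threshold is
crossed: strength continues to update under the same rules (a failure can
drop it back below θ, at which point penalties resume), and points are 0
while *s* ≥ θ, including the corner case of a user who enacted on all 7
onboarding days (initial strength 1; no capping).

**Ceiling-boundary guard.** The closed-form count takes a logarithm
ratio; floating point can land exactly on an integer boundary. The
implementation therefore adjusts the ceiling result by at most a step in
each direction until it matches the iterative definition (smallest *n*
with (1 − *s*)(1 − α)<sup>n</sup> ≤ 1 − θ + eps) exactly. The brute-force
oracle never calls the closed-form code paths — the duplication is the
point — and caps iteration at 10<sup>6</sup> steps, raising on overflow,
because α near 0 makes the count diverge.

**Session-engine ordering.** Points are computed on the *pre-update*
strength (the point equation is a function of the state in which the
action was taken); the strength update follows. Missing report days
change nothing: no penalty, no update, just a gap in the log.

## Synthetic agents and the trial simulator

The simulator is a testbed, not a fitted behavioral model. A simulated
user is purely myopic: each day they compare the immediate utility of
enacting, U₁ = −effort_weight · (1 − *s*) + v · feedback(*s*, 1), with
skipping, U₀ = v · feedback(*s*, 0), and enact with probability
logistic(β(U₁ − U₀)); β = ∞ means argmax with ties breaking toward the
costless skip. The feedback term is the engine's points in the optimized
arm, a fixed point-equivalent text bonus (+1 positive / 0 neutral) in the
text arm, and 0 in the baseline arm. Defaults v = 0.15,
effort_weight = 1, β = 3 were chosen once so that all three arms produce
interior (non-degenerate) enactment rates; they encode no empirical
claim. With v = 1 and β = ∞ the optimized-arm agent enacts at every
strength below θ — the incentive-alignment property the point equation is
designed for, verified exhaustively on a grid — while the baseline agent
never enacts.

The trial mirrors the three-arm, 21-day design: initial strengths are
drawn as k/7 with k uniform on 0..4 (the support of the onboarding
question), and each participant receives a deterministic substream
derived from (root seed, participant index), so enlarging an arm never
reshuffles earlier participants. What passing simulator tests show is
that the *incentive structure* orders the arms as intended for myopic
agents; they say nothing about human effect sizes, adherence, dropout,
or engagement — real participants are not myopic utility maximizers, and
no quantitative match to field data is attempted or implied.

## Session engine

The chatbot logic is transport-agnostic: time is a day index plus
clock-time labels (9 PM reminder, a check-in window of 30 minutes to 2.5
hours after the trigger moment), with no real scheduler — an adapter can
bind it to wall clock or a messaging platform later. Sessions are
event-sourced: the append-only JSONL log is ground truth, and
`replay_log` re-derives the final state from onboarding plus report
events alone; a property test checks replay ≡ incremental state over
random report sequences in all three conditions. Of the configurable
texts, only "That's wonderful!", "Okay. Keep going tomorrow!", the
neutral "OK", and two of the eight trigger moments are the deployed
wording; the remaining phrases and triggers are synthetic placeholders,
marked as such in the defaults. Positive phrases cycle deterministically
(counter mod 5); random cycling would change no scores.

## Problem sizes

The test suite verifies closed forms against brute force on 1000-point
grids across nine (α, θ) combinations, runs 1000 random event-sourcing
sessions, and replicates the 3 × 50-participant, 21-day trial across ten
seeds; the whole suite runs in a few seconds on one CPU.

## Limitations

- The value model assumes follow-through (always-enact); it is not a
  general MDP solver and does not model lapses after the goal, an
  explicit health-state variable, or per-user learning of α or θ.
- One binary decision per day; multiple daily opportunities, partial
  enactment, and missed check-ins with penalties are out of scope.
- The agent model is an engineered stress-test population, not a
  calibrated model of human participants.
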