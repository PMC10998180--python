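# habitpoints

Optimized gamification for digital behavior-change interventions: a point
engine that rewards each daily action with its *long-term* value, so that
even a purely myopic user — someone who only cares about today's feedback —
is incentivized to build the habit that is best for them in the long run.

The package is for developers and researchers building habit trackers,
coaching chatbots, and similar digital health tools, and for anyone who
wants to study or extend the underlying incentive-design idea.

## The model

Habit formation is modeled as a one-dimensional Markov decision process.
The state is a habit strength *s* ∈ [0, 1]. Each day the user either
enacts the behavior (*a* = 1), which moves the strength to
*s* + α(1 − *s*), or fails to (*a* = 0), which decays it to *s*(1 − α).
The habit counts as cultivated once *s* reaches a threshold θ, earning a
goal reward *r*<sub>goal</sub>; enacting costs effort −(1 − *s*), skipping
is free.

For a user who follows through, the value-to-go from strength *s* is

  *V*\*(*s*) = *r*<sub>goal</sub> − Σ<sub>k&lt;n</sub> (1 − *s*<sub>k</sub>) = *r*<sub>goal</sub> − (1 − *s*)(1 − (1 − α)<sup>n</sup>)/α,

where *n*(*s*; θ) is the number of enactments still needed to reach θ.
The long-term benefit of an action is the value difference it induces,
*f*(*s*, *a*) = *V*\*(*s*′) − *V*\*(*s*); for enactment this collapses to
the closed form *f*(*s*, 1) = 1 − *s*. The points shown to the user are

  points(*s*, *a*) = ⌊*M* · *f*(*s*, *a*)⌋ (integerized; truncation toward zero by default),

a potential-based shaping of the reward: the maximal award *M* goes to
enacting at strength 0, awards shrink to 0 at the threshold, and failures
cost roughly *M* · *s* points. Around the engine the package provides a
brute-force verification oracle, a myopic-agent simulator with a
three-arm synthetic trial (optimized points, text-only feedback,
baseline), and a transport-agnostic chatbot session engine with an
event-sourced JSONL log.

## Worked example

A user who drank water on 2 of the previous 7 days starts at strength
2/7. With the default parameters (α = 0.1, θ = 0.9, *M* = 13):

```sh
$ habitpoints points --strength 0.2857142857 --action 1
9
$ habitpoints points --strength 0.2857142857 --action 0
-4
```

Enacting on the first day earns 9 points (13 × (1 − 2/7) ≈ 9.29,
truncated); failing loses 4 (13 × *f*(2/7, 0) ≈ −4.52, truncated toward
zero). The same numbers flow through the chatbot session engine:

```sh
$ habitpoints session --days-last-week 2 --reports 1,0
day 1: Did you accomplish your goal today to drink 1.0 glasses of water
day 1: That's wonderful!
day 1: I am glad to grant you 9 points for keeping a good habit! Your total score is 9 points
day 1: Remember your intention: when my wake-up alarm rings, I will drink 1.0 glasses of water
day 2: Did you accomplish your goal today to drink 1.0 glasses of water
day 2: Okay. Keep going tomorrow!
day 2: You lost 5 points. Your total score is 4 points
day 2: Remember your intention: when my wake-up alarm rings, I will drink 1.0 glasses of water
final strength 0.321429, score 4
```

(The day-2 penalty is 5, not 4, because the day-1 enactment raised the
strength to ≈ 0.357 first.) Other commands: `habitpoints curve` writes
the points-vs-strength CSV, `habitpoints verify` checks every closed form
against brute-force iteration, `habitpoints simulate-trial` runs a
synthetic three-arm trial of simulated myopic users, and
`habitpoints replay` recomputes a session's final state from its JSONL
log. A trial config is a YAML document with keys `arms`, `n_per_arm`,
`days`, `params` (`alpha`, `theta`, `max_points`, `goal_reward`,
`rounding_mode`), `agent` (`point_utility`, `effort_weight`,
`choice_sharpness`, `text_bonus_positive`, `text_bonus_neutral`), and
`initial_days_range`.

The library API mirrors the CLI:

```python
from habitpoints import ModelParams, compute_points, n_to_goal

params = ModelParams()          # alpha=0.1, theta=0.9, M=13
compute_points(2 / 7, 1, params)  # 9
n_to_goal(0.09, params)           # 21 enactments still needed
```

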