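"""Transport-agnostic chatbot session logic.

Re-implements the conversational core of a habit-coaching chatbot: the
user onboards by choosing a daily trigger moment, an amount of water, and
reporting how often they already drank it in the previous week (which
initializes the habit strength at n/7).  Each evening the bot reminds
them of their intention, later asks whether they followed through, and
responds with condition-specific feedback:

- ``optimized``: a congratulatory or encouraging text plus the integer
  points computed by the point engine, with a running score ledger;
- ``text_feedback``: the same texts but no points;
- ``baseline``: a bare neutral acknowledgment ("OK") and no reminders.

Time is modeled as a day index plus clock-time labels; there is no real
scheduler, which keeps every path unit-testable.  Sessions are
event-sourced: an append-only log of :class:`EventRecord` rows is the
ground truth, and :func:`replay_log` re-derives the final state from the
log alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable, Sequence

from habitpoints.model import (
    HabitState,
    ModelParams,
    apply_report,
    init_strength,
)

CONDITIONS = frozenset({"optimized", "text_feedback", "baseline"})

EVENT_KINDS = ("onboarded", "reminder_sent", "checkin_asked", "report", "feedback_sent")
_KIND_RANK = {k: i for i, k in enumerate(EVENT_KINDS)}

# Two trigger moments are the deployed bot's own wording; the remaining
# six are synthetic placeholders standing in for its unpublished list.
DEFAULT_TRIGGER_MOMENTS = (
    "when my wake-up alarm rings",
    "when I have the first bite of my lunch",
    "when I brush my teeth in the morning [placeholder]",
    "when I sit down at my desk [placeholder]",
    "when I take my lunch break [placeholder]",
    "when I get home from work [placeholder]",
    "when I start preparing dinner [placeholder]",
    "when I set my alarm for the next day [placeholder]",
)

# "That's wonderful!" is the deployed bot's wording; the other four
# congratulatory phrases are synthetic placeholders.
DEFAULT_POSITIVE_PHRASES = (
    "That's wonderful!",
    "Great job! [placeholder]",
    "Well done! [placeholder]",
    "Fantastic! [placeholder]",
    "Keep it up! [placeholder]",
)

NEGATIVE_TEXT = "Okay. Keep going tomorrow!"
NEUTRAL_TEXT = "OK"

DEFAULT_TEMPLATES: dict[str, str] = {
    **{f"positive_{i}": phrase for i, phrase in enumerate(DEFAULT_POSITIVE_PHRASES)},
    "negative": NEGATIVE_TEXT,
    "neutral": NEUTRAL_TEXT,
    "points_awarded": (
        "I am glad to grant you {points} points for keeping a good habit! "
        "Your total score is {total} points"
    ),
    "points_lost": "You lost {points} points. Your total score is {total} points",
    "reminder": "Remember your intention: {trigger}, I will drink {amount} glasses of water",
    "checkin": "Did you accomplish your goal today to drink {amount} glasses of water",
}


class SessionValidationError(ValueError):
    """Invalid session input or malformed event log."""

    def __init__(self, message_key: str, detail: str = ""):
        self.message_key = message_key
        super().__init__(f"{message_key}: {detail}" if detail else message_key)


@dataclass(frozen=True)
class SessionConfig:
    """Static configuration of one chatbot session."""

    condition: str = "optimized"
    trigger_moments: tuple[str, ...] = DEFAULT_TRIGGER_MOMENTS
    reminder_clock_time: str = "21:00"
    checkin_window_minutes: tuple[int, int] = (30, 150)
    starting_score: int = 0
    params: ModelParams = field(default_factory=ModelParams)
    message_templates: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TEMPLATES))

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise SessionValidationError("invalid_condition", repr(self.condition))
        lo, hi = self.checkin_window_minutes
        if not lo < hi:
            raise SessionValidationError("invalid_checkin_window", f"{lo} >= {hi}")

    def render(self, key: str, **kwargs) -> str:
        return self.message_templates[key].format(**kwargs)


@dataclass
class EventRecord:
    """One row of the append-only session log."""

    participant: str
    day: int
    event_kind: str
    enacted: int | None = None
    points_delta: int | None = None
    strength_before: float | None = None
    strength_after: float | None = None
    score_after: int | None = None
    message_key: str | None = None

    def __post_init__(self) -> None:
        if self.event_kind not in EVENT_KINDS:
            raise SessionValidationError("invalid_event_kind", repr(self.event_kind))
        if self.day < 0:
            raise SessionValidationError("invalid_day", repr(self.day))
        if self.event_kind == "report" and self.enacted not in (0, 1):
            raise SessionValidationError("report_missing_enacted", f"day {self.day}")

    def to_json(self) -> str:
        return json.dumps({k: v for k, v in asdict(self).items() if v is not None})

    @classmethod
    def from_json(cls, line: str) -> "EventRecord":
        return cls(**json.loads(line))


def onboard(
    trigger_choice: str,
    amount_glasses: float,
    days_last_week: int,
    config: SessionConfig,
    participant: str = "user",
) -> tuple[HabitState, EventRecord]:
    """Start a session: validate the plan, initialize strength at n/7."""
    if trigger_choice not in config.trigger_moments:
        raise SessionValidationError("invalid_trigger", repr(trigger_choice))
    if not amount_glasses > 0:
        raise SessionValidationError("invalid_amount", repr(amount_glasses))
    try:
        strength = init_strength(days_last_week)
    except ValueError as exc:
        raise SessionValidationError("invalid_days_last_week", str(exc)) from exc
    state = HabitState(strength=strength, score=config.starting_score, day=0)
    event = EventRecord(
        participant=participant,
        day=0,
        event_kind="onboarded",
        strength_after=strength,
        score_after=config.starting_score,
        message_key="onboarded",
    )
    return state, event


def select_feedback_text(report: int, condition: str, rotation_state: int) -> str:
    """Message key for a report's feedback text.

    Positive texts cycle deterministically through the five
    congratulatory phrases (index = counter mod 5); the failure text is
    fixed.  The baseline condition always acknowledges neutrally.
    """
    if rotation_state < 0:
        raise ValueError(f"rotation_state must be nonnegative, got {rotation_state}")
    if condition == "baseline":
        return "neutral"
    if report == 1:
        return f"positive_{rotation_state % len(DEFAULT_POSITIVE_PHRASES)}"
    return "negative"


def daily_step(
    state: HabitState,
    report: int,
    config: SessionConfig,
    rotation_state: int = 0,
    participant: str = "user",
    trigger: str | None = None,
    amount: float = 1.0,
) -> tuple[HabitState, list[EventRecord], list[str]]:
    """Process one day's check-in and feedback.

    Points (optimized condition only) are computed on the pre-update
    strength; the strength update follows.  Returns the new state, the
    day's events (check-in, report, feedback, and — outside the baseline —
    the next day's reminder), and the rendered messages.
    """
    day = state.day + 1
    events: list[EventRecord] = []
    messages: list[str] = []

    events.append(EventRecord(participant=participant, day=day, event_kind="checkin_asked", message_key="checkin"))
    messages.append(config.render("checkin", amount=amount))

    new_state, feedback = apply_report(state, report, config.params)
    text_key = select_feedback_text(report, config.condition, rotation_state)

    if config.condition == "optimized":
        points = feedback.points_delta
        score_after = new_state.score
        events.append(
            EventRecord(
                participant=participant,
                day=day,
                event_kind="report",
                enacted=report,
                points_delta=points,
                strength_before=feedback.strength_before,
                strength_after=feedback.strength_after,
                score_after=score_after,
            )
        )
        messages.append(config.message_templates[text_key])
        if report == 1:
            messages.append(config.render("points_awarded", points=points, total=score_after))
        else:
            messages.append(config.render("points_lost", points=abs(points), total=score_after))
        events.append(
            EventRecord(
                participant=participant,
                day=day,
                event_kind="feedback_sent",
                points_delta=points,
                score_after=score_after,
                message_key=text_key,
            )
        )
    else:
        # no points outside the optimized condition; score stays put
        new_state = HabitState(strength=new_state.strength, score=state.score, day=day)
        events.append(
            EventRecord(
                participant=participant,
                day=day,
                event_kind="report",
                enacted=report,
                strength_before=feedback.strength_before,
                strength_after=feedback.strength_after,
                score_after=new_state.score,
            )
        )
        messages.append(config.message_templates[text_key])
        events.append(
            EventRecord(
                participant=participant,
                day=day,
                event_kind="feedback_sent",
                score_after=new_state.score,
                message_key=text_key,
            )
        )

    if config.condition != "baseline":
        events.append(
            EventRecord(participant=participant, day=day + 1, event_kind="reminder_sent", message_key="reminder")
        )
        messages.append(
            config.render("reminder", trigger=trigger or config.trigger_moments[0], amount=amount)
        )

    return new_state, events, messages


def replay_log(events: Sequence[EventRecord], config: SessionConfig) -> HabitState:
    """Re-derive the final session state from the event log alone.

    Only the onboarding record and the report records matter; the
    recomputed strength and score must match the incrementally maintained
    state (event-sourcing consistency).  Raises on out-of-order or
    malformed logs, naming the first offending record.
    """
    if not events:
        raise SessionValidationError("empty_log")
    if events[0].event_kind != "onboarded":
        raise SessionValidationError("log_must_start_with_onboarding", f"got {events[0].event_kind!r}")

    prev_key = (-1, -1)
    for i, ev in enumerate(events):
        key = (ev.day, _KIND_RANK[ev.event_kind])
        if key < prev_key:
            raise SessionValidationError(
                "out_of_order_event", f"record {i} ({ev.event_kind}, day {ev.day})"
            )
        prev_key = key

    onboarded = events[0]
    if onboarded.strength_after is None or onboarded.score_after is None:
        raise SessionValidationError("onboarding_missing_state", "record 0")
    state = HabitState(strength=onboarded.strength_after, score=onboarded.score_after, day=0)
    for ev in events[1:]:
        if ev.event_kind != "report":
            continue
        new_state, feedback = apply_report(state, ev.enacted, config.params)
        if config.condition != "optimized":
            new_state = HabitState(strength=new_state.strength, score=state.score, day=new_state.day)
        state = new_state
    return state


def write_jsonl(events: Iterable[EventRecord], path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(ev.to_json() + "\n")


def read_jsonl(path) -> list[EventRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(EventRecord.from_json(line))
    return records


class Session:
    """Stateful convenience wrapper maintaining the log and phrase rotation."""

    def __init__(self, config: SessionConfig, participant: str = "user"):
        self.config = config
        self.participant = participant
        self.state: HabitState | None = None
        self.log: list[EventRecord] = []
        self._positive_count = 0
        self.trigger: str | None = None
        self.amount: float = 1.0

    def onboard(self, trigger_choice: str, amount_glasses: float, days_last_week: int) -> HabitState:
        state, event = onboard(trigger_choice, amount_glasses, days_last_week, self.config, self.participant)
        self.state = state
        self.trigger = trigger_choice
        self.amount = amount_glasses
        self.log.append(event)
        return state

    def report(self, enacted: int) -> list[str]:
        if self.state is None:
            raise SessionValidationError("not_onboarded")
        self.state, events, messages = daily_step(
            self.state,
            enacted,
            self.config,
            rotation_state=self._positive_count,
            participant=self.participant,
            trigger=self.trigger,
            amount=self.amount,
        )
        if enacted == 1 and self.config.condition != "baseline":
            self._positive_count += 1
        self.log.extend(events)
        return messages

    def replay(self) -> HabitState:
        return replay_log(self.log, self.config)
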