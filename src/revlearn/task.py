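"""Probabilistic reversal learning (PRL) task engine.

Two stimuli ("A", "B") are presented on every trial; one is designated
*correct* and pays a win with high probability, the other with low
probability. After a run of consecutive correct choices (the *reversal
criterion*, drawn anew for each episode) the contingency silently flips,
up to a maximum number of reversals. The engine simulates this
environment trial by trial and records everything needed for model
fitting and behavioural summaries.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

STIMULI = ("A", "B")

__all__ = [
    "STIMULI",
    "TaskConfig",
    "ReversalState",
    "TrialRecord",
    "TrialContext",
    "Session",
    "BehavioralSummary",
    "draw_reversal_criterion",
    "apply_choice",
    "run_session",
    "summarize_behavior",
    "expected_trial_duration",
    "other_stimulus",
]


def other_stimulus(stimulus: str) -> str:
    if stimulus == "A":
        return "B"
    if stimulus == "B":
        return "A"
    raise ValueError(f"unknown stimulus id: {stimulus!r}")


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the PRL environment.

    Defaults reproduce the standard 60-trial design: 75/25 win
    contingencies, reversal after 5 or 6 consecutive correct choices,
    at most 10 reversals. Timing fields are metadata used only for
    :func:`expected_trial_duration`; the simulation does not wait.
    """

    n_trials: int = 60
    p_win_correct: float = 0.75
    p_win_incorrect: float = 0.25
    reversal_criteria: tuple[int, ...] = (5, 6)
    max_reversals: int = 10
    win_value: float = 1.0
    loss_value: float = -1.0
    display_win_amount: float = 0.5  # yuan, display only
    response_window_ms: float = 1500.0
    highlight_ms: float = 500.0
    outcome_delay_range_ms: tuple[float, float] = (500.0, 1500.0)
    outcome_display_ms: float = 1000.0
    iti_range_ms: tuple[float, float] = (500.0, 1500.0)

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")
        if not (0.0 < self.p_win_incorrect < self.p_win_correct < 1.0):
            raise ValueError(
                "require 0 < p_win_incorrect < p_win_correct < 1, got "
                f"({self.p_win_incorrect}, {self.p_win_correct})"
            )
        crits = tuple(self.reversal_criteria)
        if len(crits) == 0:
            raise ValueError("reversal_criteria must be non-empty")
        if any((not isinstance(c, (int, np.integer))) or c < 1 for c in crits):
            raise ValueError("reversal_criteria must be positive integers")
        if self.max_reversals < 0:
            raise ValueError("max_reversals must be >= 0")
        object.__setattr__(self, "reversal_criteria", crits)


@dataclass
class ReversalState:
    """Bookkeeping for the hidden contingency schedule."""

    correct_stimulus: str
    consecutive_correct: int = 0
    current_criterion: int = 5
    reversals_so_far: int = 0

    def validate(self, config: TaskConfig) -> None:
        if self.correct_stimulus not in STIMULI:
            raise ValueError(f"unknown stimulus id: {self.correct_stimulus!r}")
        if not (0 <= self.consecutive_correct < self.current_criterion):
            raise ValueError("consecutive_correct out of range")
        if self.reversals_so_far > config.max_reversals:
            raise ValueError("reversals_so_far exceeds max_reversals")


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int  # 1-based
    choice: str
    outcome: float  # win_value or loss_value
    correct_stimulus_at_trial: str
    was_correct_choice: bool
    reversal_occurred_after: bool
    responded: bool = True
    rt_ms: float = 1500.0


@dataclass(frozen=True)
class TrialContext:
    """What a choice policy sees before choosing on a trial."""

    trial_index: int
    history: tuple[TrialRecord, ...]
    correct_stimulus: str  # ground truth; only oracle policies may peek


@dataclass
class Session:
    participant_id: str
    trials: list[TrialRecord]
    config: TaskConfig = field(default_factory=TaskConfig)
    seed: int | None = None

    def __post_init__(self) -> None:
        for t, rec in enumerate(self.trials, start=1):
            if rec.trial_index != t:
                raise ValueError(
                    f"trial_index must increase from 1; found {rec.trial_index} at position {t}"
                )

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def choices(self) -> list[str]:
        return [t.choice for t in self.trials]

    @property
    def outcomes(self) -> np.ndarray:
        return np.array([t.outcome for t in self.trials], dtype=float)


@dataclass(frozen=True)
class BehavioralSummary:
    participant_id: str
    n_trials: int
    accuracy: float
    n_reversals: int
    mean_rt_ms: float


def draw_reversal_criterion(rng: np.random.Generator, config: TaskConfig) -> int:
    """Draw the next reversal criterion uniformly from the configured set."""
    crits = config.reversal_criteria
    if len(crits) == 0:
        raise ValueError("reversal_criteria must be non-empty")
    return int(crits[rng.integers(len(crits))])


def apply_choice(
    state: ReversalState,
    choice: str,
    rng: np.random.Generator,
    config: TaskConfig,
) -> tuple[float, ReversalState, bool]:
    """Resolve one choice: sample the outcome and advance the reversal state.

    Returns ``(outcome, new_state, reversal_occurred)``. "Consecutive
    correct" counts choices of the currently correct stimulus, not
    rewarded trials, so probabilistic losses on correct choices still
    advance the run. When the run reaches the criterion and the
    reversal cap has not been hit, the contingency flips immediately,
    the counter resets and a fresh criterion is drawn.
    """
    if choice not in STIMULI:
        raise ValueError(f"unknown stimulus id: {choice!r}")
    state.validate(config)

    correct = choice == state.correct_stimulus
    p_win = config.p_win_correct if correct else config.p_win_incorrect
    outcome = config.win_value if rng.random() < p_win else config.loss_value

    new_state = dataclasses.replace(state)
    reversal = False
    if correct:
        new_state.consecutive_correct += 1
        if new_state.consecutive_correct >= new_state.current_criterion:
            if new_state.reversals_so_far < config.max_reversals:
                reversal = True
                new_state.correct_stimulus = other_stimulus(new_state.correct_stimulus)
                new_state.reversals_so_far += 1
                new_state.current_criterion = draw_reversal_criterion(rng, config)
            # counter resets either way: the run is complete
            new_state.consecutive_correct = 0
    else:
        new_state.consecutive_correct = 0
    return outcome, new_state, reversal


Policy = Callable[[TrialContext], str]


def run_session(
    policy: Policy,
    config: TaskConfig | None = None,
    seed: int | None = None,
    participant_id: str = "sim",
    rng: np.random.Generator | None = None,
) -> Session:
    """Simulate one full PRL session under a choice policy.

    ``policy`` is called once per trial with a :class:`TrialContext`
    and must return a stimulus id. The initial correct stimulus and the
    first criterion are drawn from the session RNG, so a fixed ``seed``
    reproduces the session exactly for a deterministic policy.
    """
    config = config or TaskConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    state = ReversalState(
        correct_stimulus=STIMULI[rng.integers(2)],
        current_criterion=draw_reversal_criterion(rng, config),
    )
    records: list[TrialRecord] = []
    for t in range(1, config.n_trials + 1):
        ctx = TrialContext(
            trial_index=t,
            history=tuple(records),
            correct_stimulus=state.correct_stimulus,
        )
        try:
            choice = policy(ctx)
        except Exception as exc:  # annotate with trial context
            raise RuntimeError(f"policy failed on trial {t}") from exc
        if choice not in STIMULI:
            raise ValueError(f"policy returned unknown stimulus id {choice!r} on trial {t}")
        correct_now = state.correct_stimulus
        was_correct = choice == correct_now
        outcome, state, reversal = apply_choice(state, choice, rng, config)
        records.append(
            TrialRecord(
                trial_index=t,
                choice=choice,
                outcome=outcome,
                correct_stimulus_at_trial=correct_now,
                was_correct_choice=was_correct,
                reversal_occurred_after=reversal,
            )
        )
    return Session(participant_id=participant_id, trials=records, config=config, seed=seed)


def summarize_behavior(session: Session) -> BehavioralSummary:
    """Accuracy, achieved reversal count and mean RT over responded trials."""
    if len(session.trials) == 0:
        raise ValueError("session has no trials")
    n = len(session.trials)
    accuracy = sum(t.was_correct_choice for t in session.trials) / n
    n_reversals = sum(t.reversal_occurred_after for t in session.trials)
    rts = [t.rt_ms for t in session.trials if t.responded]
    mean_rt = float(np.mean(rts)) if rts else float("nan")
    return BehavioralSummary(
        participant_id=session.participant_id,
        n_trials=n,
        accuracy=accuracy,
        n_reversals=n_reversals,
        mean_rt_ms=mean_rt,
    )


def expected_trial_duration(config: TaskConfig | None = None) -> float:
    """Expected duration of one trial in ms (uniform delays enter at their midpoint)."""
    config = config or TaskConfig()
    return (
        config.response_window_ms
        + config.highlight_ms
        + 0.5 * (config.outcome_delay_range_ms[0] + config.outcome_delay_range_ms[1])
        + config.outcome_display_ms
        + 0.5 * (config.iti_range_ms[0] + config.iti_range_ms[1])
    )
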