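"""Asymmetric Rescorla-Wagner model with softmax choice.

The model carries one expected value EV per stimulus, initialised to 0.
On each trial the prediction error PE = R - EV(chosen) is computed from
the outcome R (+1 win, -1 loss) and the chosen stimulus's value is
updated by EV <- EV + alpha * PE, where the reward learning rate
``alpha_pos`` applies when PE > 0 and the punishment learning rate
``alpha_neg`` when PE <= 0. Choice probabilities follow a softmax over
the two values with inverse temperature beta:

    P(A) = 1 / (1 + exp(-beta * (EV_A - EV_B)))

The unchosen stimulus's value is carried forward unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import STIMULI, Session, TrialContext

# Floor on choice probabilities before taking logs; guards extreme-beta
# proposals during inference without materially changing the likelihood.
PROB_FLOOR = 1e-12

__all__ = [
    "AgentParameters",
    "LatentValues",
    "RLPolicy",
    "prediction_error",
    "update_expected_value",
    "choice_probability",
    "simulate_choice",
    "session_log_likelihood",
    "trajectory",
]


@dataclass(frozen=True)
class AgentParameters:
    """Native-scale parameter triple (alpha+, alpha-, beta)."""

    alpha_pos: float
    alpha_neg: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_pos <= 1.0):
            raise ValueError(f"alpha_pos must be in [0, 1], got {self.alpha_pos}")
        if not (0.0 <= self.alpha_neg <= 1.0):
            raise ValueError(f"alpha_neg must be in [0, 1], got {self.alpha_neg}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha_pos, self.alpha_neg, self.beta], dtype=float)


@dataclass
class LatentValues:
    """Expected values per stimulus plus the last prediction error."""

    ev: dict[str, float] = field(default_factory=lambda: {"A": 0.0, "B": 0.0})
    pe_last: float = 0.0


def prediction_error(outcome: float, ev_prev: float) -> float:
    """PE = R - EV(previous)."""
    return outcome - ev_prev


def update_expected_value(ev_prev: float, pe: float, params: AgentParameters) -> float:
    """One Rescorla-Wagner update of the chosen stimulus's value.

    Positive prediction errors use the reward rate; zero or negative
    prediction errors use the punishment rate.
    """
    alpha = params.alpha_pos if pe > 0 else params.alpha_neg
    return ev_prev + alpha * pe


def choice_probability(ev_a: float, ev_b: float, beta: float) -> float:
    """Softmax probability of choosing A; P(B) = 1 - P(A)."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    # logistic of beta * (EV_A - EV_B), computed stably
    x = beta * (ev_a - ev_b)
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    z = np.exp(x)
    return z / (1.0 + z)


def simulate_choice(
    latent: LatentValues, params: AgentParameters, rng: np.random.Generator
) -> str:
    """Sample a stimulus from the softmax policy over the current values."""
    p_a = choice_probability(latent.ev["A"], latent.ev["B"], params.beta)
    return "A" if rng.random() < p_a else "B"


class RLPolicy:
    """Softmax Rescorla-Wagner agent usable as a task-engine policy.

    Maintains its own latent values; when called with a
    :class:`~revlearn.task.TrialContext` it first ingests any trials it
    has not seen yet (learning from its own past choices/outcomes) and
    then samples a choice.
    """

    def __init__(self, params: AgentParameters, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.latent = LatentValues()
        self._seen = 0

    def _ingest(self, history) -> None:
        for rec in history[self._seen :]:
            ev_prev = self.latent.ev[rec.choice]
            pe = prediction_error(rec.outcome, ev_prev)
            self.latent.ev[rec.choice] = update_expected_value(ev_prev, pe, self.params)
            self.latent.pe_last = pe
        self._seen = len(history)

    def __call__(self, ctx: TrialContext) -> str:
        self._ingest(ctx.history)
        return simulate_choice(self.latent, self.params, self.rng)


def session_log_likelihood(
    session: Session,
    params: AgentParameters,
    censor_nonresponse: bool = False,
) -> float:
    """Log-likelihood of a session's choice sequence under the model.

    Values are initialised to 0 for both stimuli at the first trial.
    For each trial the log-probability of the *actually chosen*
    stimulus under the current values is accumulated, then the chosen
    stimulus's value is updated with the observed outcome.

    With ``censor_nonresponse`` the computer-selected choices on
    non-response trials are dropped from the sum (values still update).
    """
    if len(session.trials) == 0:
        raise ValueError("session has no trials")
    ev = {"A": 0.0, "B": 0.0}
    total = 0.0
    for rec in session.trials:
        if rec.choice not in STIMULI:
            raise ValueError(f"malformed session: unknown choice {rec.choice!r}")
        p_a = choice_probability(ev["A"], ev["B"], params.beta)
        p_chosen = p_a if rec.choice == "A" else 1.0 - p_a
        if rec.responded or not censor_nonresponse:
            total += np.log(max(p_chosen, PROB_FLOOR))
        pe = prediction_error(rec.outcome, ev[rec.choice])
        ev[rec.choice] = update_expected_value(ev[rec.choice], pe, params)
    return float(total)


def trajectory(session: Session, params: AgentParameters) -> pd.DataFrame:
    """Per-trial latent series: EVs before choice, PE, and choice probabilities.

    Columns: trial, choice, outcome, ev_a, ev_b, pe, p_a, p_chosen.
    Summing ``log(p_chosen)`` reproduces :func:`session_log_likelihood`.
    """
    if len(session.trials) == 0:
        raise ValueError("session has no trials")
    ev = {"A": 0.0, "B": 0.0}
    rows = []
    for rec in session.trials:
        p_a = choice_probability(ev["A"], ev["B"], params.beta)
        p_chosen = p_a if rec.choice == "A" else 1.0 - p_a
        pe = prediction_error(rec.outcome, ev[rec.choice])
        rows.append(
            {
                "trial": rec.trial_index,
                "choice": rec.choice,
                "outcome": rec.outcome,
                "ev_a": ev["A"],
                "ev_b": ev["B"],
                "pe": pe,
                "p_a": p_a,
                "p_chosen": p_chosen,
            }
        )
        ev[rec.choice] = update_expected_value(ev[rec.choice], pe, params)
    return pd.DataFrame(rows)
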