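import numpy as np
import pytest

from revlearn.model import AgentParameters, RLPolicy
from revlearn.task import Session, TaskConfig, TrialRecord, run_session


def make_session(choices, outcomes, participant_id="toy"):
    """Assemble a Session directly from choice/outcome sequences."""
    records = []
    for t, (c, o) in enumerate(zip(choices, outcomes), start=1):
        records.append(
            TrialRecord(
                trial_index=t,
                choice=c,
                outcome=float(o),
                correct_stimulus_at_trial="A",
                was_correct_choice=c == "A",
                reversal_occurred_after=False,
            )
        )
    return Session(participant_id=participant_id, trials=records)


@pytest.fixture
def toy_session():
    """3-trial session used for hand-unrolled likelihood checks."""
    return make_session(["A", "A", "B"], [1.0, -1.0, 1.0])


@pytest.fixture
def group_mean_params():
    return AgentParameters(alpha_pos=0.72, alpha_neg=0.54, beta=1.36)


@pytest.fixture
def simulated_session(group_mean_params):
    rng = np.random.default_rng(7)
    return run_session(RLPolicy(group_mean_params, rng), TaskConfig(), rng=rng)


@pytest.fixture
def simulated_sessions(group_mean_params):
    """Ten 60-trial sessions at the group-mean parameters."""
    out = []
    for i in range(10):
        rng = np.random.default_rng(100 + i)
        out.append(
            run_session(
                RLPolicy(group_mean_params, rng),
                TaskConfig(),
                participant_id=f"p{i}",
                rng=rng,
            )
        )
    return out
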