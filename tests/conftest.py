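import numpy as np
import pytest

from revpredict import agents, task_engine


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def block_config():
    return task_engine.BlockConfig()


@pytest.fixture
def ideal_agent():
    return agents.get_preset("ideal")


@pytest.fixture
def reward_focused_agent():
    return agents.get_preset("reward_focused")


def make_trial(
    trial_index,
    outcome_valence="reward",
    correct=True,
    expectedness="expected",
    response=None,
    rt_ms=700.0,
    outcome_delivered=True,
    block_id=0,
    stage_index=0,
):
    """Hand-construct a minimal TrialRecord for scoring tests."""
    if response is None:
        if correct:
            response = outcome_valence
        else:
            response = "punishment" if outcome_valence == "reward" else "reward"
    return task_engine.TrialRecord(
        block_id=block_id,
        trial_index=trial_index,
        highlighted="face",
        stimulus_repetition=None,
        position_top="face",
        response=response,
        rt_ms=rt_ms if response != "too_late" else None,
        correct=correct and response != "too_late",
        outcome_valence=outcome_valence,
        outcome_delivered=outcome_delivered,
        expectedness=expectedness if outcome_delivered else None,
        onset_ms=4000.0 * trial_index + 700.0,
        stimulus_onset_ms=4000.0 * trial_index,
        stage_index=stage_index,
    )
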