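"""Generative models of subject behavior on the prediction task.

Three strategies:

``ideal``
    Maintains a belief about the deterministic stimulus–outcome map,
    updated one-shot from every observed outcome, and predicts the
    believed outcome of the highlighted stimulus.  Errors are injected at
    parameterized rates: a *switch error* (responding from the
    pre-reversal belief) on the trial after an unexpected outcome, then
    *perseveration* continuing with a per-trial probability that depends
    on the valence the subject has to predict, and rare *lapses*
    elsewhere.

``wsls``
    Win-stay/lose-shift: repeats the previous button press after a reward
    and switches after a punishment, ignoring the stimulus entirely.

``reward_focused``
    Instrumental-like bias on top of ``ideal``: responses with the
    punishment button are slowed by ``rt_punish_button_delta_ms``
    (treating the reward button as a prepotent GO response and the
    punishment button as its withheld NOGO alternative), and
    perseveration is elevated when punishment must be predicted
    (``p_persev_given_predict_punish`` > ``p_persev_given_predict_reward``).

Response times are lognormal around ``rt_base_ms`` with additive
millisecond shifts, truncated to the response window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import exp, log
from typing import Optional

import numpy as np

STRATEGIES = ("ideal", "wsls", "reward_focused", "always_wrong")


@dataclass(frozen=True)
class AgentParams:
    strategy: str = "ideal"
    p_switch_error: float = 0.0
    p_persev_given_predict_reward: float = 0.0
    p_persev_given_predict_punish: float = 0.0
    p_lapse: float = 0.0
    p_too_late: float = 0.0
    rt_base_ms: float = 700.0
    rt_sigma: float = 0.2
    rt_punish_button_delta_ms: float = 0.0
    rt_reward_after_UR_delta_ms: float = 0.0  # negative = faster

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        for name in (
            "p_switch_error", "p_persev_given_predict_reward",
            "p_persev_given_predict_punish", "p_lapse", "p_too_late",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.rt_base_ms <= 0:
            raise ValueError("rt_base_ms must be positive")


#: Named parameter sets.  ``human_like`` is tuned only qualitatively to the
#: ordering of observed human effects (near-zero non-switch errors, high
#: switch-error rate, few perseverative errors, punishment-button slowing),
#: not fitted to any subject data.
PRESETS: dict[str, AgentParams] = {
    "ideal": AgentParams(strategy="ideal"),
    "wsls": AgentParams(strategy="wsls", p_lapse=0.02, p_too_late=0.01),
    "reward_focused": AgentParams(
        strategy="reward_focused",
        p_switch_error=0.45,
        p_persev_given_predict_reward=0.15,
        p_persev_given_predict_punish=0.35,
        p_lapse=0.005,
        p_too_late=0.01,
        rt_base_ms=740.0,
        rt_sigma=0.18,
        rt_punish_button_delta_ms=25.0,
        rt_reward_after_UR_delta_ms=-45.0,
    ),
    "valence_neutral": AgentParams(
        strategy="reward_focused",
        p_switch_error=0.45,
        p_persev_given_predict_reward=0.25,
        p_persev_given_predict_punish=0.25,
        p_lapse=0.005,
        p_too_late=0.01,
        rt_base_ms=740.0,
        rt_sigma=0.18,
    ),
    "human_like": AgentParams(
        strategy="reward_focused",
        p_switch_error=0.5,
        p_persev_given_predict_reward=0.06,
        p_persev_given_predict_punish=0.14,
        p_lapse=0.001,
        p_too_late=0.01,
        rt_base_ms=750.0,
        rt_sigma=0.18,
        rt_punish_button_delta_ms=25.0,
        rt_reward_after_UR_delta_ms=-45.0,
    ),
}


def get_preset(name: str) -> AgentParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown agent preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


@dataclass
class AgentState:
    """Mutable per-block agent state (belief, recency, perseveration)."""

    believed_reward_stimulus: Optional[str]  # None until first outcome seen
    last_response: Optional[str] = None
    last_outcome: Optional[str] = None
    persev_mode: bool = False
    stale_reward_stimulus: Optional[str] = None  # pre-reversal belief

    @staticmethod
    def initial(rng: np.random.Generator) -> "AgentState":
        return AgentState(believed_reward_stimulus=None)

    def believed_outcome(self, highlighted: str) -> Optional[str]:
        if self.believed_reward_stimulus is None:
            return None
        return "reward" if highlighted == self.believed_reward_stimulus else "punishment"


def _other(valence: str) -> str:
    return "punishment" if valence == "reward" else "reward"


def _draw_rt(
    params: AgentParams,
    response: str,
    is_switch_trial: bool,
    preceding_outcome: Optional[str],
    rng: np.random.Generator,
    response_window_ms: float = 1500.0,
) -> float:
    rt = exp(log(params.rt_base_ms) + params.rt_sigma * rng.standard_normal())
    if response == "punishment":
        rt += params.rt_punish_button_delta_ms
    if is_switch_trial and preceding_outcome == "reward" and response == "reward":
        rt += params.rt_reward_after_UR_delta_ms
    return float(min(max(rt, 150.0), response_window_ms))


def respond(
    state: AgentState,
    params: AgentParams,
    highlighted: str,
    is_switch_trial: bool,
    rng: np.random.Generator,
) -> tuple[str, float]:
    """One response: a predicted valence (or ``too_late``) and an RT.

    Mutates ``state.persev_mode`` (entered on an injected switch error,
    left on the first post-switch correct response).
    """
    if rng.random() < params.p_too_late:
        state.persev_mode = False
        return "too_late", float("nan")

    preceding = state.last_outcome

    if params.strategy == "wsls":
        if state.last_response in ("reward", "punishment") and state.last_outcome:
            if state.last_outcome == "reward":
                prediction = state.last_response
            else:
                prediction = _other(state.last_response)
        else:
            prediction = "reward" if rng.random() < 0.5 else "punishment"
        if rng.random() < params.p_lapse:
            prediction = _other(prediction)
        return prediction, _draw_rt(params, prediction, is_switch_trial, preceding, rng)

    # ideal / reward_focused: predict the believed outcome, with errors
    believed = state.believed_outcome(highlighted)
    if believed is None:
        prediction = "reward" if rng.random() < 0.5 else "punishment"
        return prediction, _draw_rt(params, prediction, is_switch_trial, preceding, rng)

    if params.strategy == "always_wrong":
        # diagnostic worst case: contradicts its own (correct) belief
        prediction = _other(believed)
        return prediction, _draw_rt(params, prediction, is_switch_trial, preceding, rng)

    prediction = believed
    if is_switch_trial:
        state.persev_mode = False
        if rng.random() < params.p_switch_error:
            # respond from the stale, pre-reversal belief
            prediction = _other(believed)
            state.persev_mode = True
    elif state.persev_mode:
        p_cont = (
            params.p_persev_given_predict_punish
            if believed == "punishment"
            else params.p_persev_given_predict_reward
        )
        if rng.random() < p_cont:
            prediction = _other(believed)
        else:
            state.persev_mode = False
    elif rng.random() < params.p_lapse:
        prediction = _other(believed)

    return prediction, _draw_rt(params, prediction, is_switch_trial, preceding, rng)


def update_belief(
    state: AgentState,
    highlighted: str,
    outcome: str,
    response: Optional[str] = None,
) -> AgentState:
    """One-shot deterministic belief update from an observed outcome.

    Observing ``highlighted -> outcome`` implies the complementary mapping
    for the other stimulus; an unexpected outcome therefore flips the
    belief about both stimuli at once.
    """
    from .task_engine import STIMULI

    new_reward_stim = (
        highlighted
        if outcome == "reward"
        else (STIMULI[1] if highlighted == STIMULI[0] else STIMULI[0])
    )
    if new_reward_stim != state.believed_reward_stimulus:
        state.stale_reward_stimulus = state.believed_reward_stimulus
    state.believed_reward_stimulus = new_reward_stim
    if response is not None:
        state.last_response = response
    state.last_outcome = outcome
    return state
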