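"""Deterministic-contingency reversal prediction task engine.

On each trial one of two stimuli (face or scene) is highlighted and the
subject predicts whether it will be followed by reward or punishment.  One
stimulus is deterministically rewarded, the other punished; the delivered
outcome depends only on the highlighted stimulus, never on the response.
After a criterion run of consecutive correct predictions (4, 5 or 6, drawn
fresh each stage) the contingency silently reverses; the first outcome
delivered in the new stage is the *unexpected* outcome (UR or UP) that
signals the reversal.  A block ends after ``max_trials`` trials or after a
run of ``quit_after_consecutive_errors`` incorrect responses.

Timing reproduces the scanner-locked trial envelope: the outcome appears at
response time and lasts 500 ms, the screen then stays clear for the rest of
the response window, the next stimulus waits for the following scanner
pulse (TR grid) plus a jitter of 500 or 1500 ms, which yields
inter-stimulus intervals between 3000 and 5000 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .agents import AgentParams

STIMULI = ("face", "scene")
#: Event codes: (un)expected reward / punishment.
TRIAL_TYPES = ("UR", "UP", "ER", "EP")


class ConfigurationError(ValueError):
    """Invalid block or run configuration."""


class InputError(ValueError):
    """Invalid runtime input (e.g. out-of-range RT)."""


@dataclass(frozen=True)
class BlockConfig:
    """Parameters of one experimental block.

    Defaults are the printed task parameters: 150-trial blocks, automatic
    quit after 10 consecutive errors, criterion set {4, 5, 6}, TR 2000 ms,
    1500 ms response window, 500 ms outcome, post-pulse jitter 500/1500 ms.
    """

    max_trials: int = 150
    quit_after_consecutive_errors: int = 10
    criterion_set: tuple[int, ...] = (4, 5, 6)
    tr_ms: int = 2000
    response_window_ms: int = 1500
    outcome_duration_ms: int = 500
    post_pulse_jitter_set_ms: tuple[int, ...] = (500, 1500)
    reward_button: str = "left"  # counterbalance flag; cosmetic
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.max_trials < 1:
            raise ConfigurationError("max_trials must be >= 1")
        if self.quit_after_consecutive_errors < 1:
            raise ConfigurationError("quit_after_consecutive_errors must be >= 1")
        if not self.criterion_set or any(c < 1 for c in self.criterion_set):
            raise ConfigurationError("criterion_set must be nonempty with values >= 1")
        if any(j >= self.tr_ms for j in self.post_pulse_jitter_set_ms):
            raise ConfigurationError("jitter values must be < tr_ms")
        if self.response_window_ms <= 0 or self.tr_ms <= 0:
            raise ConfigurationError("durations must be positive")


@dataclass
class StageState:
    """State of the current contingency stage.

    ``contingency`` names the reward-associated stimulus; the other
    stimulus is punished.  ``stage_index`` 0 is the acquisition stage.
    """

    stage_index: int
    contingency: str  # stimulus id mapped to reward
    criterion: int
    consecutive_correct: int = 0
    first_outcome_pending: bool = field(default=True)

    @property
    def punished_stimulus(self) -> str:
        return STIMULI[1] if self.contingency == STIMULI[0] else STIMULI[0]


@dataclass(frozen=True)
class TrialRecord:
    """One completed trial, outcome-event centric."""

    block_id: int
    trial_index: int
    highlighted: str
    stimulus_repetition: Optional[bool]  # defined only right after an unexpected outcome
    position_top: str  # cosmetic: which stimulus was drawn on top
    response: str  # "reward" | "punishment" | "too_late"
    rt_ms: Optional[float]
    correct: bool
    outcome_valence: str  # delivered (or withheld, if too_late) outcome
    outcome_delivered: bool
    expectedness: Optional[str]  # "expected" | "unexpected"; None if no outcome shown
    onset_ms: float  # outcome (feedback) onset from block start
    stimulus_onset_ms: float
    stage_index: int


def draw_criterion(criterion_set: Sequence[int], rng: np.random.Generator) -> int:
    """Uniform i.i.d. draw of the stage's consecutive-correct criterion."""
    return int(rng.choice(np.asarray(criterion_set)))


def deliver_outcome(stage: StageState, highlighted: str) -> str:
    """Outcome valence for the highlighted stimulus: contingency only.

    The response never influences the outcome (the task is Pavlovian:
    subjects predict, they do not choose).
    """
    return "reward" if highlighted == stage.contingency else "punishment"


def advance_stage(
    stage: StageState, correct: bool, rng: np.random.Generator,
    criterion_set: Sequence[int] = (4, 5, 6),
) -> StageState:
    """Update the consecutive-correct counter; reverse when criterion is met.

    A correct response increments the counter; an incorrect one resets it.
    Reaching the criterion starts a new stage with the contingency flipped,
    a fresh criterion draw, and the first-outcome-of-stage flag set (that
    next outcome will be labeled unexpected).
    """
    if not correct:
        stage.consecutive_correct = 0
        return stage
    stage.consecutive_correct += 1
    if stage.consecutive_correct < stage.criterion:
        return stage
    return StageState(
        stage_index=stage.stage_index + 1,
        contingency=stage.punished_stimulus,
        criterion=draw_criterion(criterion_set, rng),
    )


def select_highlight(
    stage: StageState,
    prev_trial: Optional[TrialRecord],
    rng: np.random.Generator,
) -> tuple[str, Optional[bool]]:
    """Choose the highlighted stimulus for the next trial.

    Immediately after an unexpected outcome the highlighted stimulus equals
    the stimulus paired with that outcome on exactly 50% of trials
    (stimulus repetition); otherwise the choice is uniform and the
    repetition flag is undefined (None).
    """
    if (
        prev_trial is not None
        and prev_trial.outcome_delivered
        and prev_trial.expectedness == "unexpected"
    ):
        repeat = bool(rng.random() < 0.5)
        if repeat:
            return prev_trial.highlighted, True
        other = STIMULI[1] if prev_trial.highlighted == STIMULI[0] else STIMULI[0]
        return other, False
    return STIMULI[int(rng.random() < 0.5)], None


def schedule_timing(
    stimulus_onset_ms: float,
    rt_ms: float,
    config: BlockConfig,
    rng: np.random.Generator,
) -> float:
    """Inter-stimulus interval from this stimulus onset to the next.

    Outcome (500 ms) at response, screen clear for the remaining response
    window, wait for the next scanner pulse (TR grid from block start),
    then a 500/1500 ms jitter.  Because outcome + clear always ends exactly
    ``response_window + outcome_duration`` after stimulus onset and
    stimulus onsets sit at pulse + jitter, the ISI lands in [3000, 5000] ms.
    """
    if not (0 <= rt_ms <= config.response_window_ms):
        raise InputError(f"rt_ms={rt_ms} outside [0, {config.response_window_ms}]")
    clear_end = stimulus_onset_ms + rt_ms + config.outcome_duration_ms + (
        config.response_window_ms - rt_ms
    )
    tr = config.tr_ms
    next_pulse = float(np.ceil(clear_end / tr) * tr)
    jitter = float(rng.choice(np.asarray(config.post_pulse_jitter_set_ms)))
    return next_pulse + jitter - stimulus_onset_ms


def run_block(
    config: BlockConfig,
    agent: "AgentParams",
    rng: Optional[np.random.Generator] = None,
    block_id: int = 0,
) -> list[TrialRecord]:
    """Simulate one complete block with the given agent.

    The block ends when ``max_trials`` is reached or the agent has made
    ``quit_after_consecutive_errors`` consecutive incorrect responses
    (too-late responses count as incorrect).  Stage transitions occur
    exactly when the consecutive-correct count reaches the stage's
    criterion; the first outcome delivered in each stage with index >= 1
    is labeled unexpected.  The acquisition stage's first outcome is
    expected: it follows no criterion.
    """
    from .agents import AgentState, respond, update_belief

    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    stage = StageState(
        stage_index=0,
        contingency=STIMULI[int(rng.random() < 0.5)],
        criterion=draw_criterion(config.criterion_set, rng),
    )
    stage.first_outcome_pending = False  # acquisition start follows no criterion

    state = AgentState.initial(rng)
    trials: list[TrialRecord] = []
    prev: Optional[TrialRecord] = None
    onset = float(rng.choice(np.asarray(config.post_pulse_jitter_set_ms)))
    consecutive_errors = 0

    for t in range(config.max_trials):
        highlighted, repetition = select_highlight(stage, prev, rng)
        position_top = STIMULI[int(rng.random() < 0.5)]
        outcome = deliver_outcome(stage, highlighted)
        is_switch_trial = (
            prev is not None
            and prev.outcome_delivered
            and prev.expectedness == "unexpected"
        )
        prediction, rt = respond(state, agent, highlighted, is_switch_trial, rng)

        too_late = prediction == "too_late"
        delivered = not too_late  # "too late!" replaces the feedback
        correct = (not too_late) and prediction == outcome
        if delivered:
            expectedness = (
                "unexpected" if stage.first_outcome_pending else "expected"
            )
            stage.first_outcome_pending = False
        else:
            expectedness = None

        rt_eff = rt if not too_late else float(config.response_window_ms)
        rec = TrialRecord(
            block_id=block_id,
            trial_index=t,
            highlighted=highlighted,
            stimulus_repetition=repetition,
            position_top=position_top,
            response=prediction,
            rt_ms=None if too_late else rt,
            correct=correct,
            outcome_valence=outcome,
            outcome_delivered=delivered,
            expectedness=expectedness,
            onset_ms=onset + rt_eff,
            stimulus_onset_ms=onset,
            stage_index=stage.stage_index,
        )
        trials.append(rec)

        if delivered:
            state = update_belief(state, highlighted, outcome, prediction)
        else:  # no feedback shown: nothing to learn from
            state.last_response = None
            state.last_outcome = None

        consecutive_errors = 0 if correct else consecutive_errors + 1
        if consecutive_errors >= config.quit_after_consecutive_errors:
            break

        stage = advance_stage(stage, correct, rng, config.criterion_set)
        onset += schedule_timing(onset, rt_eff, config, rng)
        prev = rec

    return trials


# ---------------------------------------------------------------------------
# BIDS-style events I/O

EVENT_COLUMNS = [
    "onset", "duration", "trial_type", "response_time",
    "accuracy", "stage_index", "stimulus_repetition",
]


def trials_to_events(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Code delivered outcomes into the four trial types (UR/UP/ER/EP).

    Onsets are outcome onsets in seconds from block start with zero
    duration.  Too-late trials show no feedback and therefore contribute
    no outcome event.
    """
    rows = []
    for tr in trials:
        if not tr.outcome_delivered:
            continue
        code = ("U" if tr.expectedness == "unexpected" else "E") + (
            "R" if tr.outcome_valence == "reward" else "P"
        )
        rows.append(
            {
                "onset": tr.onset_ms / 1000.0,
                "duration": 0.0,
                "trial_type": code,
                "response_time": np.nan if tr.rt_ms is None else tr.rt_ms / 1000.0,
                "accuracy": int(tr.correct),
                "stage_index": tr.stage_index,
                "stimulus_repetition": (
                    np.nan if tr.stimulus_repetition is None
                    else int(tr.stimulus_repetition)
                ),
            }
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events_tsv(events: pd.DataFrame, path) -> None:
    """Write a BIDS-style events.tsv (tab-separated, missing values 'n/a')."""
    events.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    missing = set(EVENT_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise InputError(f"events table missing required columns: {sorted(missing)}")
    bad = set(df["trial_type"].unique()) - set(TRIAL_TYPES)
    if bad:
        raise InputError(f"unknown trial_type values: {sorted(bad)}")
    return df
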