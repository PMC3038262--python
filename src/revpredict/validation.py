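"""Parameter-recovery validation: cohort-level replicates.

These helpers run many independent simulated cohorts and summarize how
often the analysis recovers the generative structure — the detection rate
for real effects and the false-positive rate under matched null
generators.  They are the package's calibration surface; the test suite
asserts on their output.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import agents, bold, glm, pipeline, scoring, task_engine
from .agents import AgentParams
from .task_engine import BlockConfig


def behavioral_cohort_pvalues(
    agent: AgentParams,
    seed: int,
    n_subjects: int = 16,
    n_blocks: int = 6,
    config: Optional[BlockConfig] = None,
) -> dict[str, float]:
    """Uncorrected p-values of the perseveration 2×2 RM-ANOVA for one
    simulated cohort (effects: preceding valence, predicted valence,
    interaction)."""
    config = config or BlockConfig()
    cells = []
    for rng in pipeline.subject_rngs(seed, n_subjects):
        blocks = pipeline.simulate_subject_behavior(config, agent, n_blocks, rng)
        cells.append(scoring.perseveration_cells(pipeline.score_subject(blocks)))
    cells = np.asarray(cells)
    keep = ~np.isnan(cells).any(axis=1)
    res = scoring.rm_anova_2x2(cells[keep])
    return {
        "preceding": res["main_A"][3],
        "predicted": res["main_B"][3],
        "interaction": res["interaction"][3],
        "n_complete_subjects": int(keep.sum()),
    }


def glm_cohort_results(
    seed: int,
    preset: str = "region_dissociation",
    n_subjects: int = 16,
    n_blocks: int = 2,
    noise_sd: float = 1.0,
    agent: Optional[AgentParams] = None,
    fwe_method: str = "bonferroni",
) -> pd.DataFrame:
    """Group contrast table for one simulated cohort (behavior + BOLD)."""
    agent = agent or agents.get_preset("reward_focused")
    profiles = bold.make_profiles(preset, noise_sd=noise_sd)
    effects = []
    for rng in pipeline.subject_rngs(seed, n_subjects):
        blocks = pipeline.simulate_subject_behavior(BlockConfig(), agent, n_blocks, rng)
        ev = [task_engine.trials_to_events(b) for b in blocks]
        effects.append(
            pipeline.subject_contrast_effects(
                ev, profiles, rng, contrasts=tuple(glm.CONTRASTS)
            )
        )
    return pipeline.group_contrast_stats(
        effects, fwe_method=fwe_method, rng=np.random.default_rng(seed + 7)
    )


def dissociation_recovered(group: pd.DataFrame, alpha: float = 0.05) -> dict[str, bool]:
    """Check the qualitative regional pattern in one cohort's group table:
    a valence-specific response only in the PDS-like region, unexpectedness
    responses in both striatal regions, and an amygdala deactivation for
    unexpected punishment."""
    g = group.set_index(["contrast", "roi"])

    def row(c, r):
        return g.loc[(c, r)]

    vs_pds = row("valence_specific", "pds")
    vs_avs = row("valence_specific", "avs")
    return {
        "valence_specific_pds_significant": bool(vs_pds["p_fwe"] < alpha),
        "valence_specific_avs_null": bool(
            vs_avs["p_fwe"] >= alpha and abs(vs_avs["t"]) < 4.0
        ),
        "nonspecific_avs_significant": bool(row("nonspecific", "avs")["p_fwe"] < alpha),
        "nonspecific_pds_significant": bool(row("nonspecific", "pds")["p_fwe"] < alpha),
        "amygdala_up_vs_ep_negative": bool(
            row("punishment_reversal", "amygdala")["mean_effect"] < 0
            and row("punishment_reversal", "amygdala")["p_fwe"] < alpha
        ),
    }


def post_unexpected_repetition_rate(
    seed: int,
    min_reversals: int = 10000,
    agent: Optional[AgentParams] = None,
) -> tuple[float, int]:
    """Long-run proportion of post-unexpected trials that repeat the
    stimulus paired with the unexpected outcome.

    Simulates whole blocks with a competent agent until at least
    ``min_reversals`` post-unexpected trials have been observed; returns
    (proportion, count).
    """
    agent = agent or agents.get_preset("reward_focused")
    rng = np.random.default_rng(seed)
    cfg = BlockConfig()
    flags: list[bool] = []
    while len(flags) < min_reversals:
        for t in task_engine.run_block(cfg, agent, rng=rng):
            if t.stimulus_repetition is not None:
                flags.append(t.stimulus_repetition)
    return float(np.mean(flags)), len(flags)
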