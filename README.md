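# revpredict

Simulation and analysis pipeline for **prediction-based reversal
learning** with interleaved reward- and punishment-driven reversals.

On every trial a subject sees a face and a scene, one of them highlighted,
and predicts whether the highlighted stimulus will be followed by reward
or punishment. One stimulus is deterministically rewarded, the other
punished, and the outcome never depends on the response — the task is
Pavlovian even though subjects press buttons. After 4–6 consecutive
correct predictions the contingency silently reverses; the first outcome
of the new stage is an *unexpected reward* (UR) or *unexpected punishment*
(UP) that signals the reversal. This design separates two signals that
ordinary instrumental reversal tasks confound:

- a **valence-nonspecific** surprise response, contrast
  `(UR + UP) − (ER + EP)` = `1 1 −1 −1` over (UR, UP, ER, EP), and
- a **valence-specific** response, the expectedness × valence interaction
  `(UR − ER) − (UP − EP)` = `1 −1 −1 1`,

where ER/EP are expected reward/punishment outcomes. The scientific
target pattern is a regional dissociation: an anterior ventral striatum
region that responds to unexpected outcomes of either valence, a
posterior dorsal striatum region that responds only to unexpected reward,
and an amygdala region that drops below baseline only for unexpected
punishment.

The package is aimed at researchers who want a fully synthetic,
ground-truth-controlled version of this paradigm: a task engine with the
exact trial structure and scanner-locked timing, generative behavioral
agents (ideal predictor, win-stay/lose-shift, instrumental-like
reward-focused), the switch/perseverative error taxonomy with
within-subject statistics (paired t; 2×2 repeated-measures ANOVA via
contrast scores, F = t²), ROI BOLD simulation with known betas and AR(1)
noise, and an event-related GLM (canonical double-gamma HRF + temporal
derivative, AR(1) prewhitening, random-effects second level with
Bonferroni or sign-flip max-statistic FWE over ROIs). Because the
generative truth is known, every stage is testable as a
parameter-recovery problem. See `docs/methods.md` for the model details.

## Worked example

```python
from revpredict import pipeline
from revpredict.pipeline import RunConfig

report = pipeline.run_all(RunConfig(seed=7))   # 16 subjects x 6 blocks
print(report["behavioral_counts"])
print(report["group_contrasts"])
```

With the default `reward_focused` agent and `region_dissociation` ROI
preset this prints (seed 7) per-subject means of 900 trials, ~129
reversals, ~57 switch errors and ~21 perseverative errors per session,
behavioral statistics including the punishment-button slowing
(t(15) = −16.0, reward presses faster) and the perseveration asymmetry
(predicted-valence main effect F(1,15) = 164.0, p < 10⁻⁸), and the group
contrast table, e.g.:

```
        contrast      roi  mean_effect        t  df  p_uncorrected  p_fwe
     nonspecific      avs       2.0184  47.0439  15         0.0000    0.0
     nonspecific      pds       0.9455  23.1330  15         0.0000    0.0
valence_specific      avs      -0.0236  -0.5445  15         0.5941    1.0
valence_specific      pds       0.9459  26.7972  15         0.0000    0.0
punishment_reversal amygdala   -0.8260 -24.1054  15         0.0000    0.0
```

Read: both striatal ROIs respond to unexpectedness (`nonspecific`
significant in `avs` and `pds`), only the posterior dorsal ROI carries
the valence-specific interaction, and the amygdala's unexpected-minus-
expected punishment effect is negative — the injected dissociation,
recovered from noisy simulated scans. `mean_effect` is in the simulated
signal's amplitude units (injected betas of magnitude ~1).

The same stages are available as a CLI:

```bash
revpredict simulate-behavior --config run.yaml --out out/   # BIDS-style events.tsv
revpredict score-behavior --events out/sub-01/func/*_events.tsv --out scores.csv
revpredict simulate-bold --events <events.tsv> --seed 3 --out roi.tsv
revpredict fit-glm --events <events.tsv> --roi-ts roi.tsv --out effects.csv
revpredict group-stats --effects sub1.csv --effects sub2.csv --out group.csv
revpredict run-all --config run.yaml --out out/
```

A config file is a small YAML (all sections optional except `seed`):

```yaml
seed: 7
agent: {preset: reward_focused, p_too_late: 0.02}
roi: {preset: region_dissociation, noise_sd: 1.0}
cohort: {n_subjects: 16, n_blocks: 6}
```

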