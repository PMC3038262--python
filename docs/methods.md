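# Methods

`revpredict` simulates and analyzes a Pavlovian reversal-prediction
experiment: on every trial one of two stimuli (a face and a scene) is
highlighted and the subject predicts whether it will be followed by reward
or punishment. One stimulus is deterministically rewarded and the other
punished; the delivered outcome depends only on the highlighted stimulus,
never on the response. After a run of consecutive correct predictions the
contingency silently reverses. The package generates the task, simulates
subjects, scores their errors, synthesizes region-of-interest (ROI) BOLD
signals with known ground truth, and tests whether the analysis recovers
that ground truth.

## Task engine

The engine reproduces the design parameters of the paradigm:

| parameter | default | unit | role |
|---|---|---|---|
| `max_trials` | 150 | trials | block length cap (~10 min at TR 2 s) |
| `quit_after_consecutive_errors` | 10 | trials | abort rule for non-performing subjects |
| `criterion_set` | {4, 5, 6} | correct trials | consecutive-correct criterion, drawn i.i.d. uniform per stage to keep reversals unpredictable |
| `tr_ms` | 2000 | ms | scanner repetition time; stimulus onsets are locked to the pulse grid |
| `response_window_ms` | 1500 | ms | response deadline |
| `outcome_duration_ms` | 500 | ms | feedback display |
| `post_pulse_jitter_set_ms` | {500, 1500} | ms | onset jitter after the pulse |

Trial timing: the outcome appears at the response and lasts 500 ms; the
screen then stays clear for the remainder of the response window, so every
trial occupies exactly `response_window + outcome_duration` = 2000 ms from
stimulus onset; the next stimulus starts at the following pulse plus
jitter. With onsets at pulse+jitter this yields inter-stimulus intervals
of exactly 3000, 4000 or 5000 ms — the intended 3–5 s envelope.

The first outcome delivered in each post-acquisition stage is the
*unexpected* outcome (UR or UP) signaling the reversal; all other outcomes
are expected (ER, EP). The acquisition stage's first outcome is labeled
expected: it follows no learning criterion and signals no reversal. On the
trial immediately after an unexpected outcome the highlighted stimulus
repeats the stimulus paired with that outcome on exactly 50% of draws
(`stimulus_repetition`), which decorrelates reversals from specific
response requirements.

Degenerate inputs handled explicitly: a response time outside the window
is an input error; too-late trials display no feedback, so they deliver no
outcome event, teach the agent nothing, count as incorrect for the
criterion counter and the quit rule, and contribute no RTs. If the
unexpected outcome would have been delivered on a too-late trial, the
label carries to the stage's first *delivered* outcome.

One deliberate consequence of response-independent outcomes: the
reversal-delivery trial itself is an unavoidable mismatch between the
prediction and the delivered outcome (the subject cannot foresee the
reversal), so a perfect agent produces stage lengths of 1 + criterion and
its accuracy is 100% only on scoreable (non-reversal) trials.

## Agents

Behavior is generated, not fitted. Three strategies:

- **ideal** — keeps a belief about the stimulus–outcome map, updated
  one-shot from every observed outcome (the contingencies are
  deterministic, so no learning rate is needed; an incremental RL learner
  is deliberately out of scope). Predicts the believed outcome of the
  highlighted stimulus. Errors are injected at parameterized rates:
  `p_switch_error` on the first post-reversal trial (responding from the
  stale belief), after which perseveration continues per trial with
  probability `p_persev_given_predict_reward` or `..._punish` depending on
  the valence that must be predicted, plus rare lapses (`p_lapse`)
  elsewhere and omissions (`p_too_late`).
- **wsls** — win-stay/lose-shift: repeats the previous button after
  reward, switches after punishment, ignoring the stimulus.
- **reward_focused** — ideal plus an instrumental-like GO/NOGO bias:
  punishment-button presses are slowed by `rt_punish_button_delta_ms`, and
  perseveration is elevated when punishment must be predicted. Whether
  such slowing reflects response suppression or a decision-threshold shift
  is not modeled; the shift is phenomenological.

RTs are lognormal around `rt_base_ms` (scale `rt_sigma`) with additive
millisecond shifts, truncated to (150, response window]. The
`rt_reward_after_UR_delta_ms` shift (negative = faster) applies to reward
predictions on the switch trial after an unexpected reward.

The `reward_focused` preset (`p_switch_error` 0.45, perseveration 0.15
reward / 0.35 punishment, lapse 0.005, omission 0.01, RT base 740 ms,
punish-button +25 ms) is the default generator for recovery studies: rates
large enough that a 16-subject cohort has power for the perseveration
asymmetry, orderings qualitative to the observed human pattern (near-zero
non-switch errors, frequent switch errors, slower punishment-button
presses). `valence_neutral` is the matched null (both perseveration
parameters 0.25); `human_like` scales perseveration down (~0.06/0.14) to
yield a handful of perseverative errors per session. These presets are
design choices, not fits: real subjects differ in attention, learning
noise and RT distributions, so passing recovery tests demonstrates that
the *analysis* recovers the *generative* structure, not that humans follow
these generators.

## Behavioral scoring

Each trial gets exactly one category: `reversal` (the unexpected-outcome
trial, excluded from error aggregates because the error is unavoidable),
`switch` (the trial immediately after; errors there are switch errors,
split into repetition errors — should have repeated the previous press but
alternated — and alternation errors, relative to the subject's own
previous press), `perseverative` (consecutive errors after an erroneous
switch trial, until the first correct response), and `non_switch`.

Error proportions use per-stratum denominators and are arcsine transformed
(2·arcsin(√x)) to stabilize variance. Empty strata propagate as missing
values, never zero, and subjects with missing cells are dropped listwise
from the affected test with a warning. RT means use correct responded
trials, except perseverative RTs, which are error RTs by definition.

Perseveration is cross-tabulated by preceding valence (of the signaling
unexpected outcome) × predicted valence (of the current trial). The
primary measure is a hazard-style per-trial rate — errors divided by
at-risk trials inside perseverative runs per cell — which directly
estimates the generative continuation probabilities; raw counts and
per-reversal rates are reported alongside since the field uses all three.

Statistics are classical within-subject tests: paired t, and a fully
within-subject 2×2 repeated-measures ANOVA computed as one-sample t tests
on per-subject contrast scores with F = t², df = (1, n−1), which is exact
for this design. p-values are reported uncorrected, as is conventional for
these behavioral contrasts.

## Synthetic BOLD

Each ROI is a linear-model signal: baseline + polynomial drift + per
condition beta × (canonical HRF ⊛ outcome stick function) + stationary
AR(1) Gaussian noise (marginal SD `noise_sd`, lag-1 correlation
`ar1_rho`). Signal generation uses the same canonical HRF as the analysis
(no derivative term by default); an optional latency shift
(`hrf_delay_shift_s`) exercises the temporal-derivative regressor. Blocks
default to 300 usable volumes at TR 2 s; when a block's events run longer,
the pipeline extends the scan window to cover the last response.

The `region_dissociation` preset encodes the target pattern with unit
amplitudes against `noise_sd` 1.0 and `ar1_rho` 0.3:

| ROI | UR | UP | ER | EP | interpretation |
|---|---|---|---|---|---|
| `avs` | 1.0 | 1.0 | 0 | 0 | anterior ventral striatum: valence-nonspecific surprise response |
| `pds` | 1.0 | 0 | 0 | 0 | posterior dorsal striatum: unexpected-reward-specific |
| `amygdala` | 0 | −0.8 | 0 | 0 | below baseline for unexpected punishment only |

The true amplitude and SNR of human data are unknowable from summary
statistics; these values are stated assumptions chosen so that a
16-subject cohort recovers the pattern without being trivially noiseless.
The `null` preset zeroes all betas for false-positive calibration. Not
emulated: physiological noise, motion artifacts (nuisance regressors are
exercised with simulated series), spatial structure, voxel grids.

## GLM

First level: zero-duration sticks at outcome onsets per condition,
convolved with the canonical double-gamma HRF (peak delay 6 s, undershoot
delay 16 s, unit dispersions, peak:undershoot 6:1, unit-normalized; peak
at ~5 s) and its temporal derivative (finite difference of a 0.1 s delay
shift) on a 0.1 s microtime grid, sampled at scan times. Second-order
Legendre drift per block (high-pass settings for the original acquisition
being unstated, a low-order polynomial is the conservative default),
optional motion nuisance columns, intercept last. Empty conditions are
dropped from the design and flagged. Rank deficiency raises an error
naming the collinear columns.

Fitting is OLS via `numpy.linalg.lstsq`; serial correlation is handled by
two-pass AR(1) prewhitening (estimate ρ from OLS residuals, clip to
±0.95, transform, refit), on by default and switchable to plain OLS.
Contrasts are defined over the four condition HRF columns only —
derivative columns absorb latency but do not enter contrasts (standard
practice). The four named contrasts over (UR, UP, ER, EP):
`reward_reversal` (1 0 −1 0), `punishment_reversal` (0 1 0 −1),
`nonspecific` (1 1 −1 −1), `valence_specific` (1 −1 −1 1).

The model is fitted per block and first-level effects are averaged within
subject (whether the original analysis concatenated runs or used session
regressors is unstated; per-block fitting avoids cross-block drift
assumptions). Second level: a one-sample t across subjects per ROI and
contrast, family-wise error over the ROI set by Bonferroni (default) or by
sign-flip permutation of the maximum |t| (exhaustive up to 2^n ≤ 10,000,
sampled otherwise). Voxelwise random-field correction is out of scope; at
ROI scale Bonferroni/permutation are appropriate and exactly testable.

## Validation and problem sizes

`revpredict.validation` runs cohort replicates; the test suite asserts:

- **Engine exactness** — quit rule, 150-trial blocks, 900 trials per
  6-block session, 3000–5000 ms ISIs, 50% ± 1.5% post-unexpected
  stimulus-repetition rate at ≥10,000 reversals.
- **Scoring oracles** — hand-scored sequences; F = t² to 1e−10; arcsine
  boundary identities; an independent one-sample-t oracle for paired t.
- **Behavioral recovery** — the predicted-valence perseveration effect
  detected (p < .05) in >80 of 100 cohorts of 16 subjects × 6 blocks with
  the `reward_focused` generator, and a ~5% false-positive rate over 500
  `valence_neutral` cohorts (99% binomial acceptance region).
- **GLM recovery** — noiseless simulate→fit round trip to <1e−8;
  the full regional pattern (valence-specific only in `pds`, nonspecific
  in both striatal ROIs, amygdala deactivation for unexpected punishment)
  in ≥90 of 100 cohorts of 16 subjects × 2 blocks; ~5% per-ROI type-I
  rate and controlled family-wise rate over 500 null cohorts of 16
  subjects × 1 block; permutation p equal to exhaustive enumeration at
  n = 10.

Cohort replicate sizes (2 blocks for signal cohorts, 1 for null cohorts)
were chosen as the smallest sessions at which first-level effects are
estimated cleanly; detection rates at 6 blocks are at least as high.

## Known limitations

- Agents have no incremental learning, attention lapses beyond a constant
  rate, or session effects; RT distributions are shift-lognormal only.
- BOLD simulation is per-ROI and temporal only; no spatial inference.
- The AR(1) estimate uses a single two-pass refit, adequate at these
  series lengths but not a full restricted-likelihood noise model.
- Events-table round trips lose too-late trials (they have no outcome
  event), so scoring from files can differ from in-memory scoring for
  agents with high omission rates.
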