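"""End-to-end orchestration: simulate behavior -> score -> simulate BOLD ->
GLM -> group statistics -> report bundle.

A cohort run is fully determined by ``(RunConfig, seed)``.  Per-subject
random streams are spawned deterministically from the cohort seed, so any
subject can be regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import agents, bold, glm, scoring, task_engine
from .agents import AgentParams
from .bold import ROIProfile
from .task_engine import BlockConfig, ConfigurationError

log = logging.getLogger("revpredict")

HRF_TAIL_S = 30.0  # scans appended after the last event to cover the response


@dataclass(frozen=True)
class RunConfig:
    """Cohort-level configuration (defaults: 16 subjects, 6 blocks each)."""

    task: BlockConfig = field(default_factory=BlockConfig)
    agent: AgentParams = field(default_factory=lambda: agents.get_preset("reward_focused"))
    roi_preset: str = "region_dissociation"
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    whitening: str = "ar1"
    fwe_method: str = "bonferroni"
    n_subjects: int = 16
    n_blocks: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.n_blocks < 1:
            raise ConfigurationError("n_blocks must be >= 1")

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "task": dataclasses.asdict(self.task),
                "agent": dataclasses.asdict(self.agent),
                "roi_preset": self.roi_preset,
                "noise_sd": self.noise_sd,
                "ar1_rho": self.ar1_rho,
                "whitening": self.whitening,
                "fwe_method": self.fwe_method,
                "n_subjects": self.n_subjects,
                "n_blocks": self.n_blocks,
                "seed": self.seed,
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def subject_rngs(seed: int, n_subjects: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_subjects)]


def simulate_subject_behavior(
    config: BlockConfig,
    agent: AgentParams,
    n_blocks: int,
    rng: np.random.Generator,
) -> list[list[task_engine.TrialRecord]]:
    return [
        task_engine.run_block(config, agent, rng=rng, block_id=b)
        for b in range(n_blocks)
    ]


def score_subject(blocks: Sequence[Sequence[task_engine.TrialRecord]]) -> scoring.SubjectSummary:
    scored: list[scoring.ScoredTrial] = []
    for b in blocks:
        scored.extend(scoring.classify(b))
    return scoring.summarize(scored)


def behavioral_group_stats(summaries: Sequence[scoring.SubjectSummary]) -> dict:
    """Cohort-level behavioral statistics (all p-values uncorrected).

    Runs the within-subject tests the behavioral analysis prescribes:
    button-RT paired t, switch-vs-non-switch error t, and the 2×2
    (preceding × predicted) repeated-measures ANOVA on arcsine-transformed
    perseverative error rates.
    """
    out: dict = {}

    def _rt(summary, cell):
        tab = summary.rt_means.set_index("cell")["mean_rt_ms"]
        return float(tab.loc[cell])

    def guarded(key, fn):
        """Small cohorts can lack strata; report the degeneracy, don't die."""
        try:
            out[key] = fn()
        except (scoring.DegenerateInputError, task_engine.InputError) as exc:
            log.warning("behavioral test %s skipped: %s", key, exc)
            out[key] = {"error": str(exc)}

    def rt_test():
        rew = [_rt(s, "button_reward") for s in summaries]
        pun = [_rt(s, "button_punishment") for s in summaries]
        if np.isnan(rew).any() or np.isnan(pun).any():
            raise scoring.DegenerateInputError("missing button RT cells")
        t, df, p = scoring.paired_t(rew, pun)
        return {"t": t, "df": df, "p_uncorrected": p}

    guarded("rt_reward_vs_punish_button", rt_test)

    def _err(summary, stratum):
        tab = summary.error_rates.set_index("stratum")["arcsine"]
        return float(tab.loc[stratum])

    def err_test():
        sw = [_err(s, "switch") for s in summaries]
        ns = [_err(s, "non_switch") for s in summaries]
        t, df, p = scoring.paired_t(sw, ns)
        return {"t": t, "df": df, "p_uncorrected": p}

    guarded("switch_vs_non_switch_errors", err_test)

    def persev_test():
        cells = np.array([scoring.perseveration_cells(s) for s in summaries])
        anova = scoring.cohort_rm_anova(cells, label="perseveration 2x2")
        return {
            k: {"F": v[0], "df": [v[1], v[2]], "p_uncorrected": v[3]}
            for k, v in anova.items()
        }

    guarded("perseveration_anova", persev_test)
    return out


def _block_n_scans(events: pd.DataFrame, tr_ms: float) -> int:
    last = float(events["onset"].max()) if len(events) else 0.0
    return max(
        bold.DEFAULT_N_SCANS, int(np.ceil((last + HRF_TAIL_S) / (tr_ms / 1000.0)))
    )


def subject_contrast_effects(
    block_events: Sequence[pd.DataFrame],
    profiles: Sequence[ROIProfile],
    rng: np.random.Generator,
    tr_ms: float = bold.DEFAULT_TR_MS,
    whitening: str = "ar1",
    contrasts: Sequence[str] = tuple(glm.CONTRASTS),
) -> pd.DataFrame:
    """Simulate ROI signals and fit the GLM block by block for one subject.

    Returns a tidy frame (roi, contrast, effect): first-level effects
    averaged across blocks, the subject's input to the second level.
    Also includes per-condition beta estimates as pseudo-contrasts
    ``beta_UR`` etc. (each condition versus implicit baseline).
    """
    rows = []
    for events in block_events:
        n_scans = _block_n_scans(events, tr_ms)
        X = glm.build_design(events, n_scans, tr_ms)
        for prof in profiles:
            ts = bold.simulate_roi(prof, events, tr_ms, n_scans, rng)
            fit = glm.fit(ts.values, X, whitening=whitening)
            for cname in contrasts:
                eff, _ = glm.contrast_t(fit, cname)
                rows.append({"roi": prof.name, "contrast": cname, "effect": eff})
            for k, cond in enumerate(task_engine.TRIAL_TYPES):
                vec = np.zeros(4)
                vec[k] = 1.0
                eff, _ = glm.contrast_t(fit, vec)
                rows.append({"roi": prof.name, "contrast": f"beta_{cond}", "effect": eff})
    df = pd.DataFrame(rows)
    return df.groupby(["roi", "contrast"], as_index=False)["effect"].mean()


def group_contrast_stats(
    subject_effects: Sequence[pd.DataFrame],
    fwe_method: str = "bonferroni",
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Second-level random-effects t per (roi, contrast), FWE over ROIs."""
    stacked = pd.concat(
        [df.assign(subject=i) for i, df in enumerate(subject_effects)],
        ignore_index=True,
    )
    rows = []
    for cname, grp in stacked.groupby("contrast"):
        wide = grp.pivot(index="subject", columns="roi", values="effect")
        rois = list(wide.columns)
        E = wide.to_numpy()
        for j, roi in enumerate(rois):
            res = glm.second_level(
                E[:, j],
                n_tests=len(rois),
                method=fwe_method,
                effects_matrix=E if fwe_method == "max_t_permutation" else None,
                roi_index=j,
                rng=rng,
            )
            rows.append(
                {
                    "contrast": cname,
                    "roi": roi,
                    "mean_effect": float(np.mean(E[:, j])),
                    "t": res.t,
                    "df": res.df,
                    "p_uncorrected": res.p_uncorrected,
                    "p_fwe": res.p_fwe,
                    "fwe_method": res.method,
                    "n_rois": len(rois),
                }
            )
    return pd.DataFrame(rows)


def run_all(config: RunConfig, out_dir: Optional[Path] = None) -> dict:
    """Full pipeline for one cohort; optionally writes the report bundle.

    Returns a dict with the behavioral summary and statistics, the
    ROI-by-condition beta table, and the group contrast results.
    """
    t0 = time.time()
    rngs = subject_rngs(config.seed, config.n_subjects)
    profiles = bold.make_profiles(
        config.roi_preset, noise_sd=config.noise_sd, ar1_rho=config.ar1_rho
    )

    summaries, effects, counts = [], [], []
    all_events: list[list[pd.DataFrame]] = []
    for i, rng in enumerate(rngs):
        try:
            blocks = simulate_subject_behavior(
                config.task, config.agent, config.n_blocks, rng
            )
            summaries.append(score_subject(blocks))
            ev = [task_engine.trials_to_events(b) for b in blocks]
            all_events.append(ev)
            effects.append(
                subject_contrast_effects(
                    ev, profiles, rng, config.task.tr_ms, config.whitening
                )
            )
            counts.append(summaries[-1].counts)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"pipeline failed for subject {i}: {exc}") from exc
        log.info("subject %d done (%.1fs)", i, time.time() - t0)

    try:
        behav = behavioral_group_stats(summaries)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"behavioral statistics stage failed: {exc}") from exc
    try:
        group = group_contrast_stats(
            effects, fwe_method=config.fwe_method,
            rng=np.random.default_rng(config.seed + 7),
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"group GLM stage failed: {exc}") from exc

    beta_table = (
        pd.concat([df.assign(subject=i) for i, df in enumerate(effects)])
        .query("contrast.str.startswith('beta_')")
        .groupby(["roi", "contrast"], as_index=False)["effect"]
        .agg(["mean", "sem"])
    )

    report = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "n_blocks": config.n_blocks,
        "behavioral_counts": pd.DataFrame(counts).mean().to_dict(),
        "behavioral_stats": behav,
        "group_contrasts": group,
        "roi_betas": beta_table,
        "runtime_s": time.time() - t0,
    }

    if out_dir is not None:
        _write_bundle(out_dir, config, all_events, summaries, report)
    return report


def _write_bundle(out_dir, config, all_events, summaries, report) -> None:
    out = Path(out_dir)
    deriv = out / "derivatives"
    deriv.mkdir(parents=True, exist_ok=True)
    for i, ev_blocks in enumerate(all_events):
        func = out / f"sub-{i + 1:02d}" / "func"
        func.mkdir(parents=True, exist_ok=True)
        for b, ev in enumerate(ev_blocks):
            task_engine.write_events_tsv(
                ev, func / f"sub-{i + 1:02d}_task-reversal_run-{b + 1:02d}_events.tsv"
            )
    pd.concat(
        [s.error_rates.assign(subject=i + 1) for i, s in enumerate(summaries)]
    ).to_csv(deriv / "error_rates.csv", index=False)
    pd.concat(
        [s.perseveration.assign(subject=i + 1) for i, s in enumerate(summaries)]
    ).to_csv(deriv / "perseveration.csv", index=False)
    pd.concat(
        [s.rt_means.assign(subject=i + 1) for i, s in enumerate(summaries)]
    ).to_csv(deriv / "rt_means.csv", index=False)
    report["group_contrasts"].to_csv(deriv / "group_contrasts.csv", index=False)
    report["roi_betas"].to_csv(deriv / "roi_betas.csv", index=False)
    serializable = {
        k: v
        for k, v in report.items()
        if k not in ("group_contrasts", "roi_betas")
    }
    with open(deriv / "report.json", "w") as fh:
        json.dump(serializable, fh, indent=2, default=float)
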