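"""YAML run-configuration loading.

A config file has optional sections ``task``, ``agent``, ``roi``, ``glm``
and ``cohort``; unknown keys raise, so typos fail fast.  The ``agent``
section may name a ``preset`` and then override individual fields.

Example::

    seed: 7
    task: {max_trials: 150}
    agent: {preset: reward_focused, p_too_late: 0.02}
    roi: {preset: region_dissociation, noise_sd: 1.0}
    glm: {whitening: ar1, fwe_method: bonferroni}
    cohort: {n_subjects: 16, n_blocks: 6}
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .agents import AgentParams, get_preset
from .pipeline import RunConfig
from .task_engine import BlockConfig, ConfigurationError


def _build(cls, section: dict, what: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigurationError(f"unknown {what} config keys: {sorted(unknown)}")
    # YAML lists become the tuple-typed fields
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
    }
    return cls(**coerced)


def load_config(path: str | Path, seed_override: int | None = None) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")

    task = _build(BlockConfig, raw.get("task", {}) or {}, "task")

    agent_sec = dict(raw.get("agent", {}) or {})
    preset = agent_sec.pop("preset", None)
    if preset is not None:
        agent = dataclasses.replace(get_preset(preset), **agent_sec)
    else:
        agent = _build(AgentParams, agent_sec, "agent")

    roi = dict(raw.get("roi", {}) or {})
    glm_sec = dict(raw.get("glm", {}) or {})
    cohort = dict(raw.get("cohort", {}) or {})
    seed = seed_override if seed_override is not None else raw.get("seed")
    if seed is None:
        raise ConfigurationError("a seed is mandatory for reproducibility")

    return RunConfig(
        task=task,
        agent=agent,
        roi_preset=roi.get("preset", "region_dissociation"),
        noise_sd=float(roi.get("noise_sd", 1.0)),
        ar1_rho=float(roi.get("ar1_rho", 0.3)),
        whitening=glm_sec.get("whitening", "ar1"),
        fwe_method=glm_sec.get("fwe_method", "bonferroni"),
        n_subjects=int(cohort.get("n_subjects", 16)),
        n_blocks=int(cohort.get("n_blocks", 6)),
        seed=int(seed),
    )
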