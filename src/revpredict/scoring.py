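"""Error taxonomy, transforms and within-subject statistics.

Trials are classified relative to the reversal structure:

* ``reversal`` — the trial on which the unexpected outcome itself is
  delivered.  The subject cannot foresee the reversal, so the inevitable
  mismatch on this trial is excluded from error-rate aggregates.
* ``switch`` — the trial immediately after an unexpected outcome; an
  incorrect response here is a switch error.  Switch errors are further
  flagged as repetition errors (should have repeated the previous
  response but alternated) or alternation errors (should have alternated
  but repeated).
* ``perseverative`` — consecutive errors after an erroneous switch trial,
  before the first correct response.
* ``non_switch`` — every other responded trial.

Error proportions use per-stratum denominators and are variance-stabilized
with the arcsine transform 2·arcsin(√x).  Group statistics are classical
within-subject tests: paired t, and a 2×2 repeated-measures ANOVA computed
from one-sample t-tests on per-subject contrast scores (F = t²), which for
a fully within-subject 2×2 design is exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task_engine import InputError, TrialRecord

CATEGORIES = ("reversal", "switch", "perseverative", "non_switch")
VALENCES = ("reward", "punishment")


class DegenerateInputError(ValueError):
    """A statistic is undefined for this input (e.g. zero variance)."""


@dataclass(frozen=True)
class ScoredTrial:
    trial: TrialRecord
    category: str
    preceding_valence: Optional[str]  # valence of the signaling unexpected outcome
    predicted_valence: Optional[str]  # the to-be-predicted (correct) outcome
    response_repetition_required: Optional[bool]  # switch trials only
    repetition_error: bool
    alternation_error: bool


def classify(trials: Sequence[TrialRecord]) -> list[ScoredTrial]:
    """Assign each trial to exactly one category (see module doc)."""
    prev_index: Optional[int] = None
    for tr in trials:
        if prev_index is not None and tr.trial_index <= prev_index:
            raise InputError("trials must be in block order")
        prev_index = tr.trial_index

    scored: list[ScoredTrial] = []
    pending_switch = False  # the next trial is the switch trial
    persev_run = False  # inside a run of consecutive post-switch errors
    preceding: Optional[str] = None  # valence of the signaling unexpected outcome
    prev_response: Optional[str] = None  # the subject's own previous button press

    for tr in trials:
        correct_response = tr.outcome_valence  # the to-be-predicted outcome
        rep_required: Optional[bool] = None
        rep_err = alt_err = False
        responded = tr.response in VALENCES
        is_error = responded and not tr.correct

        if tr.outcome_delivered and tr.expectedness == "unexpected":
            category = "reversal"
            persev_run = False
        elif pending_switch:
            category = "switch"
            # repetition/alternation is relative to the subject's own
            # previous press, per definitions C-D
            if prev_response is not None and responded:
                rep_required = correct_response == prev_response
                if is_error:
                    rep_err = bool(rep_required)  # should repeat, alternated
                    alt_err = not rep_required  # should alternate, repeated
            persev_run = is_error  # errors that follow are perseverative
        elif persev_run and is_error:
            category = "perseverative"
        else:
            category = "non_switch"
            persev_run = False

        scored.append(
            ScoredTrial(
                trial=tr,
                category=category,
                preceding_valence=(
                    preceding if category in ("switch", "perseverative") else None
                ),
                predicted_valence=correct_response,
                response_repetition_required=rep_required,
                repetition_error=rep_err,
                alternation_error=alt_err,
            )
        )

        if category == "reversal":
            pending_switch = True
            preceding = tr.outcome_valence
        else:
            pending_switch = False
        prev_response = tr.response if responded else None

    return scored


def arcsine_transform(x: float) -> float:
    """Variance-stabilizing transform 2·arcsin(√x) for a proportion x."""
    if not 0.0 <= x <= 1.0:
        raise InputError(f"proportion {x} outside [0, 1]")
    return 2.0 * math.asin(math.sqrt(x))


def paired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, int, float]:
    """Classical paired t-test; returns (t, df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise InputError("paired_t needs two equal-length vectors, n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0) and not np.allclose(d, 0.0):
        raise DegenerateInputError(
            "paired differences have zero variance but nonzero mean: "
            "t statistic is undefined"
        )
    if np.allclose(d, 0.0):
        return 0.0, len(d) - 1, 1.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), len(a) - 1, float(res.pvalue)


def rm_anova_2x2(cells: np.ndarray | pd.DataFrame) -> dict[str, tuple[float, int, int, float]]:
    """Fully within-subject 2×2 ANOVA via per-subject contrast scores.

    ``cells`` is n_subjects × 4 ordered (A1B1, A1B2, A2B1, A2B2).  Each
    effect is the one-sample t on the corresponding contrast score with
    F = t² and df = (1, n−1) — exact for this design.  Returns
    {effect: (F, df1, df2, p)} for ``main_A``, ``main_B``, ``interaction``.
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 2 or cells.shape[1] != 4:
        raise InputError("cells must be n_subjects x 4 (A1B1, A1B2, A2B1, A2B2)")
    if np.isnan(cells).any():
        raise InputError("missing cell values; drop incomplete subjects first")
    n = cells.shape[0]
    if n < 2:
        raise InputError("need at least 2 subjects")
    contrasts = {
        "main_A": np.array([1.0, 1.0, -1.0, -1.0]) / 2.0,
        "main_B": np.array([1.0, -1.0, 1.0, -1.0]) / 2.0,
        "interaction": np.array([1.0, -1.0, -1.0, 1.0]) / 2.0,
    }
    out = {}
    for name, c in contrasts.items():
        score = cells @ c
        sd = score.std(ddof=1)
        if sd == 0.0:
            f, p = 0.0, 1.0
        else:
            t = score.mean() / (sd / math.sqrt(n))
            f = t * t
            p = float(stats.f.sf(f, 1, n - 1))
        out[name] = (float(f), 1, n - 1, p)
    return out


# ---------------------------------------------------------------------------
# Per-subject summaries


def _proportion(k: int, n: int) -> float:
    return np.nan if n == 0 else k / n


@dataclass
class SubjectSummary:
    """Per-subject behavioral summary tables (tidy DataFrames)."""

    error_rates: pd.DataFrame  # stratum, n_trials, n_errors, proportion, arcsine
    rt_means: pd.DataFrame  # condition cell, n, mean RT (ms)
    perseveration: pd.DataFrame  # preceding x predicted tallies and rates
    counts: dict[str, int]


def summarize(scored: Sequence[ScoredTrial]) -> SubjectSummary:
    """Stratified error proportions, RT means and perseveration tallies.

    Error proportions use the stratum's own trial count as denominator;
    empty strata yield missing values (NaN), never zero.  RT means use
    correct responded trials, except perseverative-trial RTs which are by
    definition error RTs; too-late trials never contribute RTs.
    """
    rows = []
    responded = [s for s in scored if s.trial.response in VALENCES]

    def stratum(name, pred):
        sel = [s for s in responded if pred(s)]
        errs = [s for s in sel if not s.trial.correct]
        p = _proportion(len(errs), len(sel))
        rows.append(
            {
                "stratum": name,
                "n_trials": len(sel),
                "n_errors": len(errs),
                "proportion": p,
                "arcsine": np.nan if np.isnan(p) else arcsine_transform(p),
            }
        )

    stratum("switch", lambda s: s.category == "switch")
    stratum("non_switch", lambda s: s.category == "non_switch")
    for prec in VALENCES:
        stratum(
            f"switch_preceding_{prec}",
            lambda s, prec=prec: s.category == "switch" and s.preceding_valence == prec,
        )
    for pred_v in VALENCES:
        stratum(
            f"switch_predicted_{pred_v}",
            lambda s, v=pred_v: s.category == "switch" and s.predicted_valence == v,
        )
        stratum(
            f"non_switch_predicted_{pred_v}",
            lambda s, v=pred_v: s.category == "non_switch" and s.predicted_valence == v,
        )
    for prec in VALENCES:
        for pred_v in VALENCES:
            stratum(
                f"switch_prec_{prec}_pred_{pred_v}",
                lambda s, a=prec, b=pred_v: s.category == "switch"
                and s.preceding_valence == a
                and s.predicted_valence == b,
            )
    error_rates = pd.DataFrame(rows)

    # --- RT means ---------------------------------------------------------
    rt_rows = []

    def rt_cell(name, pred, errors_ok=False):
        sel = [
            s
            for s in responded
            if pred(s)
            and s.trial.rt_ms is not None
            and (errors_ok or s.trial.correct)
        ]
        rts = [s.trial.rt_ms for s in sel]
        rt_rows.append(
            {"cell": name, "n": len(rts), "mean_rt_ms": np.nan if not rts else float(np.mean(rts))}
        )

    for v in VALENCES:
        rt_cell(f"button_{v}", lambda s, v=v: s.trial.response == v)
    rt_cell("non_switch", lambda s: s.category == "non_switch")
    rt_cell("switch", lambda s: s.category == "switch")
    for prec in VALENCES:
        for pred_v in VALENCES:
            rt_cell(
                f"switch_prec_{prec}_pred_{pred_v}",
                lambda s, a=prec, b=pred_v: s.category == "switch"
                and s.preceding_valence == a
                and s.predicted_valence == b,
            )
    rt_cell("perseverative", lambda s: s.category == "perseverative", errors_ok=True)
    rt_cell(
        "response_repetition",
        lambda s: s.category == "switch" and s.response_repetition_required is True,
    )
    rt_cell(
        "response_alternation",
        lambda s: s.category == "switch" and s.response_repetition_required is False,
    )
    rt_means = pd.DataFrame(rt_rows)

    # --- perseveration, preceding x predicted -----------------------------
    # Hazard-style rate: among trials inside a perseverative run (the error
    # trials plus the run-terminating correct trial), the fraction erred,
    # per (preceding, predicted) cell.  Also reported: raw counts and the
    # per-reversal rate (errors / switch trials with that preceding valence).
    persev_rows = []
    run_trials = []  # (preceding, predicted, is_error) for trials at risk
    in_run = False
    run_preceding: Optional[str] = None
    for s in scored:
        if s.category == "switch":
            in_run = not s.trial.correct and s.trial.response in VALENCES
            run_preceding = s.preceding_valence
            continue
        if s.category == "reversal":
            in_run = False
            continue
        if in_run and s.trial.response in VALENCES:
            run_trials.append((run_preceding, s.predicted_valence, not s.trial.correct))
            if s.trial.correct:
                in_run = False

    n_switch_by_prec = {
        v: sum(1 for s in responded if s.category == "switch" and s.preceding_valence == v)
        for v in VALENCES
    }
    for prec in VALENCES:
        for pred_v in VALENCES:
            at_risk = [r for r in run_trials if r[0] == prec and r[1] == pred_v]
            errs = sum(1 for r in at_risk if r[2])
            persev_rows.append(
                {
                    "preceding": prec,
                    "predicted": pred_v,
                    "n_at_risk": len(at_risk),
                    "n_errors": errs,
                    "rate": _proportion(errs, len(at_risk)),
                    "per_reversal_rate": _proportion(errs, n_switch_by_prec[prec]),
                }
            )
    perseveration = pd.DataFrame(persev_rows)

    counts = {
        "n_trials": len(scored),
        "n_responded": len(responded),
        "n_reversals": sum(1 for s in scored if s.category == "reversal"),
        "n_switch_trials": sum(1 for s in responded if s.category == "switch"),
        "n_switch_errors": sum(
            1 for s in responded if s.category == "switch" and not s.trial.correct
        ),
        "n_perseverative_errors": sum(
            1 for s in responded if s.category == "perseverative"
        ),
        "n_repetition_errors": sum(1 for s in responded if s.repetition_error),
        "n_alternation_errors": sum(1 for s in responded if s.alternation_error),
    }
    return SubjectSummary(error_rates, rt_means, perseveration, counts)


def perseveration_cells(
    summary: SubjectSummary, measure: str = "rate", transform: bool = True
) -> np.ndarray:
    """2×2 perseveration cells ordered (RR, RP, PR, PP) by preceding×predicted."""
    tab = summary.perseveration.set_index(["preceding", "predicted"])[measure]
    cells = np.array(
        [
            tab.loc[("reward", "reward")],
            tab.loc[("reward", "punishment")],
            tab.loc[("punishment", "reward")],
            tab.loc[("punishment", "punishment")],
        ]
    )
    if transform:
        cells = np.array(
            [np.nan if np.isnan(c) else arcsine_transform(min(c, 1.0)) for c in cells]
        )
    return cells


def events_to_trials(events: pd.DataFrame, block_id: int = 0) -> list[TrialRecord]:
    """Reconstruct minimal trial records from a BIDS-style events table.

    Events code delivered outcomes only, so too-late trials are absent
    and the stimulus identity is unknown; everything the error taxonomy
    needs (outcome valence, expectedness, accuracy, RT, order) survives
    the round trip.
    """
    trials = []
    for i, row in enumerate(events.itertuples(index=False)):
        code = row.trial_type
        valence = "reward" if code[1] == "R" else "punishment"
        correct = bool(row.accuracy)
        rt = getattr(row, "response_time", np.nan)
        trials.append(
            TrialRecord(
                block_id=block_id,
                trial_index=i,
                highlighted="unknown",
                stimulus_repetition=None,
                position_top="unknown",
                response=valence if correct else (
                    "punishment" if valence == "reward" else "reward"
                ),
                rt_ms=None if pd.isna(rt) else float(rt) * 1000.0,
                correct=correct,
                outcome_valence=valence,
                outcome_delivered=True,
                expectedness="unexpected" if code[0] == "U" else "expected",
                onset_ms=float(row.onset) * 1000.0,
                stimulus_onset_ms=float(row.onset) * 1000.0,
                stage_index=int(getattr(row, "stage_index", 0)),
            )
        )
    return trials


def summarize_events(event_tables: Sequence[pd.DataFrame]) -> SubjectSummary:
    """Score one subject from their per-block events tables."""
    scored: list[ScoredTrial] = []
    for b, ev in enumerate(event_tables):
        scored.extend(classify(events_to_trials(ev, block_id=b)))
    return summarize(scored)


def cohort_rm_anova(
    cell_matrix: np.ndarray, label: str = ""
) -> dict[str, tuple[float, int, int, float]]:
    """2×2 RM-ANOVA with listwise deletion of subjects with missing cells."""
    cells = np.asarray(cell_matrix, dtype=float)
    keep = ~np.isnan(cells).any(axis=1)
    if keep.sum() < cells.shape[0]:
        warnings.warn(
            f"{label}: dropped {int((~keep).sum())} subject(s) with empty strata",
            stacklevel=2,
        )
    return rm_anova_2x2(cells[keep])
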