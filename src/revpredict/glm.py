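"""Event-related GLM for ROI time series.

First level: each outcome type (UR, UP, ER, EP) is modeled as a
zero-duration stick function at outcome onset, convolved with the
canonical double-gamma hemodynamic response function and its temporal
derivative on a 0.1 s microtime grid, then sampled at scan times.
Polynomial drift and optional nuisance (motion) columns are appended,
intercept last.  Fitting is OLS with optional two-pass AR(1)
prewhitening.  Contrasts are defined over the four condition HRF columns;
the derivative columns absorb small latency shifts but do not enter
contrasts.

Second level: random-effects one-sample t across subjects' contrast
effects, with family-wise error control across ROIs by Bonferroni or by
sign-flip permutation of the maximum statistic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task_engine import TRIAL_TYPES, InputError

MICROTIME_DT = 0.1  # s
HRF_LENGTH = 32.0  # s

#: The four canonical contrasts over (UR, UP, ER, EP) HRF columns.
CONTRASTS: dict[str, np.ndarray] = {
    "reward_reversal": np.array([1.0, 0.0, -1.0, 0.0]),
    "punishment_reversal": np.array([0.0, 1.0, 0.0, -1.0]),
    "nonspecific": np.array([1.0, 1.0, -1.0, -1.0]),
    "valence_specific": np.array([1.0, -1.0, -1.0, 1.0]),
}


class DegenerateInputError(ValueError):
    pass


def canonical_hrf(
    t: np.ndarray | float,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF, unit peak, zero at t=0.

    Difference of two gamma densities (peak at ~5 s, undershoot around
    15 s, peak:undershoot amplitude ratio 6), normalized to max 1.
    """
    t = np.asarray(t, dtype=float)
    peak = stats.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = stats.gamma.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    h = peak - under / ratio
    grid = np.arange(0.0, HRF_LENGTH, MICROTIME_DT)
    hg = stats.gamma.pdf(grid, peak_delay / peak_disp, scale=peak_disp) - (
        stats.gamma.pdf(grid, undershoot_delay / undershoot_disp, scale=undershoot_disp)
        / ratio
    )
    return h / hg.max()


@lru_cache(maxsize=8)
def _hrf_basis_cached(dt: float, delay_shift: float) -> tuple[np.ndarray, np.ndarray]:
    grid = np.arange(0.0, HRF_LENGTH, dt)
    h = canonical_hrf(grid)
    h_shift = canonical_hrf(np.maximum(grid - delay_shift, 0.0))
    d = (h - h_shift) / delay_shift
    h.setflags(write=False)
    d.setflags(write=False)
    return h, d


def hrf_basis(dt: float = MICROTIME_DT, delay_shift: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Sampled canonical HRF and its temporal derivative on the microtime grid.

    The derivative is the finite difference of a small delay shift,
    (hrf(t) − hrf(t − δ)) / δ, the standard latency basis.
    """
    return _hrf_basis_cached(float(dt), float(delay_shift))


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # n_scans x p
    columns: list[str]
    tr_ms: float
    condition_hrf_columns: list[int] = field(default_factory=list)
    empty_conditions: list[str] = field(default_factory=list)

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.columns)


def _legendre_drift(n_scans: int, order: int) -> np.ndarray:
    """Orthogonal polynomial drift columns (degree 1..order) on [-1, 1]."""
    x = np.linspace(-1.0, 1.0, n_scans)
    return np.column_stack([np.polynomial.legendre.Legendre.basis(k)(x) for k in range(1, order + 1)])


def build_design(
    events: pd.DataFrame,
    n_scans: int,
    tr_ms: float,
    nuisance: Optional[np.ndarray] = None,
    drift_order: int = 2,
    microtime_dt: float = MICROTIME_DT,
) -> DesignMatrix:
    """Design matrix from an events table (onset s, trial_type).

    One HRF and one derivative column per condition (empty conditions give
    all-zero columns, reported via the column label suffix ``:empty`` and
    dropped to keep the design full rank), then drift, nuisance, and the
    intercept last.
    """
    bad = set(events["trial_type"].unique()) - set(TRIAL_TYPES)
    if bad:
        raise InputError(f"unknown trial_type values: {sorted(bad)}")
    tr_s = tr_ms / 1000.0
    total_s = n_scans * tr_s
    if len(events) and events["onset"].max() >= total_s:
        raise InputError(
            f"event onset {events['onset'].max():.1f}s beyond scan window {total_s:.1f}s"
        )

    n_micro = int(np.ceil(total_s / microtime_dt))
    h, d = hrf_basis(microtime_dt)
    scan_idx = np.round(np.arange(n_scans) * tr_s / microtime_dt).astype(int)

    cols, labels, cond_idx = [], [], []
    empty: list[str] = []
    for cond in TRIAL_TYPES:
        onsets = events.loc[events["trial_type"] == cond, "onset"].to_numpy()
        sticks = np.zeros(n_micro)
        if len(onsets):
            idx = np.round(onsets / microtime_dt).astype(int)
            np.add.at(sticks, idx, 1.0)
        else:
            empty.append(cond)
            continue
        reg_h = np.convolve(sticks, h)[:n_micro][scan_idx]
        reg_d = np.convolve(sticks, d)[:n_micro][scan_idx]
        cond_idx.append(len(cols))
        cols.append(reg_h)
        labels.append(f"{cond}:hrf")
        cols.append(reg_d)
        labels.append(f"{cond}:derivative")

    if drift_order > 0:
        drift = _legendre_drift(n_scans, drift_order)
        for k in range(drift.shape[1]):
            cols.append(drift[:, k])
            labels.append(f"drift:{k + 1}")
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_scans:
            nuisance = nuisance.T
        if nuisance.shape[0] != n_scans:
            raise InputError("nuisance regressors must have n_scans rows")
        for k in range(nuisance.shape[1]):
            cols.append(nuisance[:, k])
            labels.append(f"nuisance:{k + 1}")
    cols.append(np.ones(n_scans))
    labels.append("intercept")

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns for the error message
        r = np.linalg.qr(X, mode="r")
        dep = [labels[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-10]
        raise InputError(f"design matrix is rank deficient; collinear columns: {dep}")
    return DesignMatrix(
        matrix=X, columns=labels, tr_ms=tr_ms,
        condition_hrf_columns=cond_idx, empty_conditions=empty,
    )


@dataclass
class FitResult:
    betas: np.ndarray
    sigma2: float
    dof: int
    design: DesignMatrix
    residuals: np.ndarray
    ar1_rho: Optional[float] = None
    #: (X'X)^-1 of the (possibly whitened) design used for the fit
    xtx_inv: Optional[np.ndarray] = None


def _ols(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int, np.ndarray]:
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = len(Y) - rank
    sigma2 = float(resid @ resid / dof) if dof > 0 else 0.0
    xtx_inv = np.linalg.pinv(X.T @ X)
    return beta, resid, sigma2, dof, xtx_inv


def fit(
    Y: np.ndarray | Sequence[float],
    X: DesignMatrix,
    whitening: str = "ar1",
) -> FitResult:
    """Least-squares fit of the design to one ROI time series.

    ``whitening='ar1'`` runs the standard two-pass scheme: OLS, estimate
    the residual lag-1 autocorrelation, transform both sides with the
    AR(1) whitening filter, refit.  ``'none'`` is plain OLS.
    """
    y = np.asarray(Y, dtype=float)
    if y.ndim != 1 or len(y) != X.n_scans:
        raise InputError("time series length must equal design rows")
    if whitening not in ("none", "ar1"):
        raise InputError(f"unknown whitening {whitening!r}")

    beta, resid, sigma2, dof, xtx_inv = _ols(y, X.matrix)
    if whitening == "none":
        return FitResult(beta, sigma2, dof, X, resid, None, xtx_inv)

    r = resid
    denom = float(r[:-1] @ r[:-1])
    rho = float(r[1:] @ r[:-1] / denom) if denom > 0 else 0.0
    rho = float(np.clip(rho, -0.95, 0.95))

    def whiten(v: np.ndarray) -> np.ndarray:
        w = v.copy().astype(float)
        w[1:] = v[1:] - rho * v[:-1]
        w[0] = v[0] * np.sqrt(1.0 - rho**2)
        return w

    yw = whiten(y)
    Xw = np.column_stack([whiten(X.matrix[:, j]) for j in range(X.matrix.shape[1])])
    beta, resid, sigma2, dof, xtx_inv = _ols(yw, Xw)
    return FitResult(beta, sigma2, dof, X, resid, rho, xtx_inv)


def contrast_t(fitres: FitResult, c: np.ndarray | str) -> tuple[float, float]:
    """First-level contrast effect and t statistic.

    ``c`` is a name from :data:`CONTRASTS` or a length-4 vector over the
    condition HRF columns (UR, UP, ER, EP); all other columns get zero
    weight.  A condition absent from the design contributes zero.
    """
    if isinstance(c, str):
        c = CONTRASTS[c]
    c = np.asarray(c, dtype=float)
    if c.shape != (4,):
        raise InputError("contrast must be a length-4 vector over (UR, UP, ER, EP)")
    X = fitres.design
    full_c = np.zeros(X.matrix.shape[1])
    for cond, w in zip(TRIAL_TYPES, c):
        try:
            j = X.columns.index(f"{cond}:hrf")
        except ValueError:
            continue
        full_c[j] = w
    effect = float(full_c @ fitres.betas)
    var = float(fitres.sigma2 * full_c @ fitres.xtx_inv @ full_c)
    t = effect / np.sqrt(var) if var > 0 else (0.0 if effect == 0 else np.inf)
    return effect, float(t)


@dataclass
class ContrastResult:
    contrast: np.ndarray
    effects: np.ndarray  # per-subject first-level effects
    t: float
    df: int
    p_uncorrected: float
    p_fwe: float
    method: str


def one_sample_t(effects: np.ndarray) -> tuple[float, int, float]:
    e = np.asarray(effects, dtype=float)
    n = len(e)
    if n < 2:
        raise InputError("need at least 2 subjects")
    sd = e.std(ddof=1)
    if sd == 0.0:
        if np.all(e == 0.0):
            return 0.0, n - 1, 1.0
        raise DegenerateInputError("zero between-subject variance with nonzero mean")
    t = e.mean() / (sd / np.sqrt(n))
    return float(t), n - 1, float(2.0 * stats.t.sf(abs(t), n - 1))


def sign_flip_pvalues(
    effects_matrix: np.ndarray,
    n_permutations: int = 10000,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """FWE-corrected p by sign-flip permutation of the maximum |t| over ROIs.

    ``effects_matrix`` is n_subjects × n_rois.  All 2^n sign patterns are
    enumerated when feasible (2^n <= n_permutations), otherwise
    n_permutations random flips are sampled.  Returns (t_obs, p_fwe).
    """
    E = np.atleast_2d(np.asarray(effects_matrix, dtype=float))
    if E.ndim != 2:
        raise InputError("effects_matrix must be n_subjects x n_rois")
    n, m = E.shape

    def tstats(M: np.ndarray) -> np.ndarray:
        sd = M.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = M.mean(axis=0) / (sd / np.sqrt(n))
        return np.where(sd == 0, 0.0, t)

    t_obs = tstats(E)
    if 2**n <= n_permutations:
        signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
    else:
        if rng is None:
            rng = np.random.default_rng()
        signs = rng.choice([1.0, -1.0], size=(n_permutations, n))
    max_abs = np.empty(len(signs))
    for i, s in enumerate(signs):
        max_abs[i] = np.abs(tstats(E * s[:, None])).max()
    p_fwe = np.array([(max_abs >= abs(t) - 1e-12).mean() for t in t_obs])
    return t_obs, p_fwe


def second_level(
    effects: np.ndarray,
    n_tests: int = 1,
    method: str = "bonferroni",
    contrast: Optional[np.ndarray] = None,
    effects_matrix: Optional[np.ndarray] = None,
    roi_index: int = 0,
    n_permutations: int = 10000,
    rng: Optional[np.random.Generator] = None,
) -> ContrastResult:
    """Random-effects group inference on per-subject contrast effects.

    ``method='bonferroni'`` multiplies the uncorrected p by ``n_tests``;
    ``method='max_t_permutation'`` uses sign-flip permutation of the
    maximum statistic over the ROIs in ``effects_matrix`` (defaults to the
    single ROI given).
    """
    e = np.asarray(effects, dtype=float)
    t, df, p_unc = one_sample_t(e)
    if method == "bonferroni":
        p_fwe = min(1.0, p_unc * n_tests)
    elif method == "max_t_permutation":
        E = e[:, None] if effects_matrix is None else np.asarray(effects_matrix)
        _, p_all = sign_flip_pvalues(E, n_permutations=n_permutations, rng=rng)
        p_fwe = float(p_all[roi_index if effects_matrix is not None else 0])
    else:
        raise InputError(f"unknown FWE method {method!r}")
    return ContrastResult(
        contrast=np.asarray(contrast) if contrast is not None else np.array([]),
        effects=e,
        t=t,
        df=df,
        p_uncorrected=p_unc,
        p_fwe=p_fwe,
        method=method,
    )
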