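"""Synthetic ROI BOLD time series with known ground truth.

Each region of interest is described by an :class:`ROIProfile`: one
response amplitude (beta) per outcome type (UR, UP, ER, EP), a baseline
level, low-order polynomial drift, and AR(1) Gaussian noise.  The signal
is generated through the same canonical-HRF linear model the analysis
fits, so with zero noise and zero drift the GLM recovers the injected
betas exactly — the package's parameter-recovery surface.

The ``region_dissociation`` preset encodes the striatal/amygdala
dissociation the pipeline is designed to recover:

* an anterior-ventral-striatum-like region responding to unexpected
  outcomes of *either* valence (valence-nonspecific),
* a posterior-dorsal-striatum-like region responding to unexpected
  reward only (valence-specific), and
* an amygdala-like region deactivating below baseline for unexpected
  punishment only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .glm import MICROTIME_DT, hrf_basis
from .task_engine import TRIAL_TYPES, ConfigurationError, InputError

DEFAULT_N_SCANS = 300  # usable volumes per block (312 acquired − 12 dummies)
DEFAULT_TR_MS = 2000.0


@dataclass(frozen=True)
class ROIProfile:
    """Ground truth for one simulated region."""

    name: str
    beta: dict[str, float]  # {UR, UP, ER, EP} -> amplitude (signal units)
    baseline: float = 100.0
    ar1_rho: float = 0.3
    noise_sd: float = 1.0
    drift_coeffs: tuple[float, ...] = ()  # polynomial in scaled time on [-1, 1]
    hrf_delay_shift_s: float = 0.0  # latency offset exercising the derivative

    def __post_init__(self) -> None:
        if not abs(self.ar1_rho) < 1.0:
            raise ConfigurationError("|ar1_rho| must be < 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        missing = set(TRIAL_TYPES) - set(self.beta)
        if missing:
            raise ConfigurationError(f"beta map missing conditions: {sorted(missing)}")

    def contrast_value(self, c: Sequence[float]) -> float:
        return float(np.dot(c, [self.beta[k] for k in TRIAL_TYPES]))


@dataclass
class ROITimeSeries:
    name: str
    values: np.ndarray
    tr_ms: float

    @property
    def n_scans(self) -> int:
        return len(self.values)


PRESET_NAMES = ("paper_dissociation", "region_dissociation", "null")


def make_profiles(
    preset: str = "region_dissociation",
    noise_sd: float = 1.0,
    ar1_rho: float = 0.3,
) -> list[ROIProfile]:
    """Named ground-truth profile sets.

    ``region_dissociation`` (alias ``paper_dissociation``): AVS-like
    region with equal UR and UP responses, PDS-like region with a UR
    response only, amygdala-like region below baseline for UP only.
    ``null``: all betas equal (zero) in all three regions.
    """
    if preset not in PRESET_NAMES:
        raise ConfigurationError(
            f"unknown preset {preset!r}; available: {PRESET_NAMES}"
        )
    drift = (0.5, -0.3)
    if preset == "null":
        zero = {k: 0.0 for k in TRIAL_TYPES}
        return [
            ROIProfile(name, zero, ar1_rho=ar1_rho, noise_sd=noise_sd, drift_coeffs=drift)
            for name in ("avs", "pds", "amygdala")
        ]
    return [
        ROIProfile(
            "avs",
            {"UR": 1.0, "UP": 1.0, "ER": 0.0, "EP": 0.0},
            ar1_rho=ar1_rho, noise_sd=noise_sd, drift_coeffs=drift,
        ),
        ROIProfile(
            "pds",
            {"UR": 1.0, "UP": 0.0, "ER": 0.0, "EP": 0.0},
            ar1_rho=ar1_rho, noise_sd=noise_sd, drift_coeffs=drift,
        ),
        ROIProfile(
            "amygdala",
            {"UR": 0.0, "UP": -0.8, "ER": 0.0, "EP": 0.0},
            ar1_rho=ar1_rho, noise_sd=noise_sd, drift_coeffs=drift,
        ),
    ]


def ar1_noise(
    n: int, rho: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) Gaussian noise with marginal standard deviation sd."""
    eps = rng.standard_normal(n)
    x = np.empty(n)
    innov_sd = np.sqrt(1.0 - rho**2)
    x[0] = eps[0]
    for t in range(1, n):
        x[t] = rho * x[t - 1] + innov_sd * eps[t]
    return sd * x


def simulate_roi(
    profile: ROIProfile,
    events: pd.DataFrame,
    tr_ms: float = DEFAULT_TR_MS,
    n_scans: int = DEFAULT_N_SCANS,
    rng: Optional[np.random.Generator] = None,
) -> ROITimeSeries:
    """Simulate one ROI's scan-by-scan signal for an events table.

    signal = baseline + drift + Σ_cond beta·(HRF ⊛ sticks) + AR(1) noise.
    With ``noise_sd=0`` and no drift the series equals the noiseless model
    prediction exactly.
    """
    if rng is None:
        rng = np.random.default_rng()
    tr_s = tr_ms / 1000.0
    total_s = n_scans * tr_s
    if len(events) and events["onset"].max() >= total_s:
        raise InputError(
            f"event onset {events['onset'].max():.1f}s beyond scan window {total_s:.1f}s"
        )

    n_micro = int(np.ceil(total_s / MICROTIME_DT))
    h, _ = hrf_basis(MICROTIME_DT)
    shift_bins = int(round(profile.hrf_delay_shift_s / MICROTIME_DT))
    scan_idx = np.round(np.arange(n_scans) * tr_s / MICROTIME_DT).astype(int)

    y = np.full(n_scans, profile.baseline, dtype=float)
    for cond in TRIAL_TYPES:
        amp = profile.beta[cond]
        onsets = events.loc[events["trial_type"] == cond, "onset"].to_numpy()
        if amp == 0.0 or len(onsets) == 0:
            continue
        sticks = np.zeros(n_micro)
        idx = np.round(onsets / MICROTIME_DT).astype(int) + shift_bins
        idx = idx[(idx >= 0) & (idx < n_micro)]
        np.add.at(sticks, idx, 1.0)
        y += amp * np.convolve(sticks, h)[:n_micro][scan_idx]

    if profile.drift_coeffs:
        x = np.linspace(-1.0, 1.0, n_scans)
        for k, coeff in enumerate(profile.drift_coeffs, start=1):
            y += coeff * x**k
    if profile.noise_sd > 0:
        y += ar1_noise(n_scans, profile.ar1_rho, profile.noise_sd, rng)
    return ROITimeSeries(name=profile.name, values=y, tr_ms=tr_ms)


def write_roi_tsv(series: Sequence[ROITimeSeries], path) -> None:
    """ROI time series as TSV, one column per region (header = ROI name)."""
    if len({s.n_scans for s in series}) > 1:
        raise InputError("all ROI series must share n_scans")
    pd.DataFrame({s.name: s.values for s in series}).to_csv(
        path, sep="\t", index=False
    )


def read_roi_tsv(path, tr_ms: float = DEFAULT_TR_MS) -> list[ROITimeSeries]:
    df = pd.read_csv(path, sep="\t")
    return [ROITimeSeries(name=c, values=df[c].to_numpy(float), tr_ms=tr_ms) for c in df.columns]


def profiles_to_json_dict(profiles: Sequence[ROIProfile]) -> dict:
    return {
        p.name: {
            "beta": p.beta,
            "baseline": p.baseline,
            "ar1_rho": p.ar1_rho,
            "noise_sd": p.noise_sd,
            "drift_coeffs": list(p.drift_coeffs),
        }
        for p in profiles
    }
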