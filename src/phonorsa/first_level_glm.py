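"""First-level GLM: HRF design matrices, high-pass filtering, AR(1) prewhitening.

Events are modeled at their onsets with their durations as boxcars on a
100 ms microtime grid, convolved with a canonical double-gamma HRF, and
sampled at the volume acquisition times (one volume per 3.95 s trial).  Each
of the 32 conditions gets one regressor (four trials: 2 repetitions x 2
exemplars); target trials get one regressor per stimulus type; the decision
cue and button presses get one regressor each — 36 task regressors per run.
Motion parameters enter as nuisance columns; the per-run mean is the session
mean; rest trials are unmodeled (implicit baseline).

Drift removal uses a discrete-cosine basis up to the cutoff frequency
(default 350 s period), projected out of design and data.  Autocorrelation is
handled by a pooled AR(1) model: a scalar lag-1 coefficient is estimated from
an ordinary fit's residuals and both sides are prewhitened by the AR(1)
inverse square-root operator (single Cochrane-Orcutt iteration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "HRFParams",
    "DesignMatrix",
    "GLMFit",
    "double_gamma_hrf",
    "build_design_matrix",
    "dct_drift_basis",
    "highpass_filter",
    "fit_glm",
    "run_glm",
]

MICROTIME_DT = 0.1  # seconds


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF parameters (SPM convention)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    ratio: float = 6.0
    duration: float = 32.0


def double_gamma_hrf(t: np.ndarray, params: HRFParams = HRFParams()) -> np.ndarray:
    """Canonical HRF evaluated at times t (seconds), peak-normalized to 1."""
    t = np.asarray(t, dtype=float)
    # shape = delay/dispersion + 1 puts the gamma mode exactly at the delay
    pos = sps.gamma.pdf(t, params.peak_delay / params.peak_disp + 1.0,
                        scale=params.peak_disp)
    neg = sps.gamma.pdf(t, params.undershoot_delay / params.undershoot_disp + 1.0,
                        scale=params.undershoot_disp)
    h = pos - neg / params.ratio
    h[t < 0] = 0.0
    peak = h.max()
    return h / peak if peak > 0 else h


@dataclass
class DesignMatrix:
    """Samples x regressors matrix with named, partitioned columns."""

    matrix: np.ndarray
    names: list[str]
    partitions: dict[str, str]  # name -> partition label
    frame_times: np.ndarray

    def __post_init__(self):
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("matrix width does not match names")
        if len(set(self.names)) != len(self.names):
            raise ValueError("regressor names must be unique")

    def columns(self, partition: str) -> list[int]:
        return [k for k, n in enumerate(self.names) if self.partitions[n] == partition]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names, index=self.frame_times)


@dataclass
class GLMFit:
    betas: np.ndarray  # (regressors, voxels)
    residuals: np.ndarray  # (samples, voxels)
    names: list[str]
    dof: int
    ar_coefficient: float

    def condition_betas(self, design: DesignMatrix) -> np.ndarray:
        return self.betas[design.columns("condition"), :]


def _convolved_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    frame_times: np.ndarray,
    hrf: HRFParams,
) -> np.ndarray:
    """HRF-convolved boxcar sampled at acquisition times (microtime grid)."""
    t_max = float(frame_times.max()) + hrf.duration + 1.0
    grid = np.arange(0.0, t_max, MICROTIME_DT)
    box = np.zeros_like(grid)
    for on, dur in zip(onsets, durations):
        if on < 0 or on > frame_times.max() + 1e-9:
            raise ValueError(f"event onset {on} outside run duration")
        a = int(np.floor(on / MICROTIME_DT))
        b = max(a + 1, int(np.ceil((on + dur) / MICROTIME_DT)))
        box[a:b] = 1.0
    kernel = double_gamma_hrf(np.arange(0.0, hrf.duration, MICROTIME_DT), hrf)
    conv = np.convolve(box, kernel)[: grid.size] * MICROTIME_DT
    idx = np.rint(frame_times / MICROTIME_DT).astype(int)
    return conv[idx]


def build_design_matrix(
    events: pd.DataFrame,
    n_volumes: int,
    tr: float = 3.95,
    hrf: HRFParams = HRFParams(),
    motion: np.ndarray | None = None,
) -> DesignMatrix:
    """Per-run design matrix from a BIDS-style events table.

    Condition regressors are ordered by first appearance of the condition
    label in canonical order of the events table's ``trial_type`` for
    ``kind == "stimulus"``; callers that need the canonical 32-condition
    order should pass events generated by :mod:`phonorsa.stimulus_design`,
    whose labels sort into it (see ``sorted`` below).
    """
    frame_times = np.arange(n_volumes) * tr
    cols, names, parts = [], [], {}

    stim = events[events["kind"] == "stimulus"]
    cond_labels = sorted(stim["trial_type"].unique(), key=_canonical_key)
    for label in cond_labels:
        ev = stim[stim["trial_type"] == label]
        cols.append(
            _convolved_regressor(
                ev["onset"].to_numpy(), ev["duration"].to_numpy(), frame_times, hrf
            )
        )
        names.append(label)
        parts[label] = "condition"

    tgt = events[events["kind"] == "target"]
    for stype in sorted(tgt["stimulus_type"].unique()):
        ev = tgt[tgt["stimulus_type"] == stype]
        name = f"target_{stype}"
        cols.append(
            _convolved_regressor(
                ev["onset"].to_numpy(), ev["duration"].to_numpy(), frame_times, hrf
            )
        )
        names.append(name)
        parts[name] = "target_by_type"

    for kind, part in (("decision", "decision_cue"), ("button", "button")):
        ev = events[events["kind"] == kind]
        if len(ev) == 0:
            continue
        cols.append(
            _convolved_regressor(
                ev["onset"].to_numpy(), ev["duration"].to_numpy(), frame_times, hrf
            )
        )
        names.append(part)
        parts[part] = part

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_volumes:
            raise ValueError("motion regressors do not match volume count")
        for k in range(motion.shape[1]):
            name = f"motion_{k + 1}"
            cols.append(motion[:, k])
            names.append(name)
            parts[name] = "motion"

    name = "session_mean"
    cols.append(np.ones(n_volumes))
    names.append(name)
    parts[name] = "session_mean"
    return DesignMatrix(np.column_stack(cols), names, parts, frame_times)


_WORD_ORDER = ("beam", "beat", "boom", "boot", "real", "reef", "rule", "roof")
_TYPE_ORDER = ("visual_speech", "auditory_speech", "dynamic_text")


def _canonical_key(label: str):
    word, rest = label.split("_", 1)
    stype, form = rest.rsplit("_", 1)
    return (_WORD_ORDER.index(word), _TYPE_ORDER.index(stype), form)


def dct_drift_basis(n: int, tr: float, cutoff: float = 350.0) -> np.ndarray:
    """Discrete-cosine drift regressors with periods longer than ``cutoff``.

    Columns are cos(pi k (2t+1) / 2n) for k = 1..K with K = floor(2 n tr /
    cutoff); the constant (k = 0) is left to the session-mean regressor.
    """
    if cutoff <= 2 * tr:
        raise ValueError("cutoff must exceed twice the TR")
    order = int(np.floor(2.0 * n * tr / cutoff))
    t = np.arange(n)
    basis = [
        np.sqrt(2.0 / n) * np.cos(np.pi * k * (2 * t + 1) / (2.0 * n))
        for k in range(1, order + 1)
    ]
    return np.column_stack(basis) if basis else np.empty((n, 0))


def highpass_filter(
    design: np.ndarray, data: np.ndarray, tr: float, cutoff: float = 350.0
) -> tuple[np.ndarray, np.ndarray, int]:
    """Project the DCT drift subspace out of design and data.

    Returns filtered design, filtered data, and the number of drift
    regressors removed (for dof accounting).
    """
    n = data.shape[0]
    C = dct_drift_basis(n, tr, cutoff)
    if C.shape[1] == 0:
        return design, data, 0
    # orthonormal columns: residual projector is I - C C'
    Q, _ = np.linalg.qr(C)
    return design - Q @ (Q.T @ design), data - Q @ (Q.T @ data), C.shape[1]


def _ar1_whiten(x: np.ndarray, rho: float) -> np.ndarray:
    out = x.astype(float).copy()
    out[1:] = x[1:] - rho * x[:-1]
    out[0] = x[0] * np.sqrt(1.0 - rho**2)
    return out


def fit_glm(
    design: DesignMatrix | np.ndarray,
    data: np.ndarray,
    tr: float = 3.95,
    highpass_cutoff: float | None = 350.0,
    ar1: str = "estimate",
) -> GLMFit:
    """Fit the linear model with optional high-pass filtering and AR(1).

    ``ar1="estimate"`` pools the lag-1 autocorrelation of ordinary residuals
    over voxels, prewhitens both sides, and refits; ``ar1="off"`` is OLS.
    """
    if isinstance(design, DesignMatrix):
        X = design.matrix
        names = design.names
    else:
        X = np.asarray(design, dtype=float)
        names = [f"x{k}" for k in range(X.shape[1])]
    Y = np.asarray(data, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n_drift = 0
    if highpass_cutoff is not None:
        # keep the session mean out of the projection (it is its own column)
        X, Y, n_drift = highpass_filter(X, Y, tr, highpass_cutoff)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [names[k] for k in range(X.shape[1]) if abs(R[k, k]) < 1e-8]
        raise np.linalg.LinAlgError(
            f"design rank deficient after filtering; collinear columns: {bad}"
        )

    def _ols(Xw, Yw):
        beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
        return beta, Yw - Xw @ beta

    beta, resid = _ols(X, Y)
    rho = 0.0
    if ar1 == "estimate":
        num = float((resid[1:] * resid[:-1]).sum())
        den = float((resid**2).sum())
        rho = 0.0 if den == 0 else np.clip(num / den, -0.99, 0.99)
        Xw = _ar1_whiten(X, rho)
        Yw = _ar1_whiten(Y, rho)
        beta, resid = _ols(Xw, Yw)
    elif ar1 != "off":
        raise ValueError("ar1 must be 'off' or 'estimate'")
    dof = Y.shape[0] - X.shape[1] - n_drift
    return GLMFit(beta, resid, names, dof, float(rho))


def run_glm(
    events: pd.DataFrame,
    data: np.ndarray,
    tr: float = 3.95,
    hrf: HRFParams = HRFParams(),
    motion: np.ndarray | None = None,
    highpass_cutoff: float = 350.0,
    ar1: str = "estimate",
) -> tuple[DesignMatrix, GLMFit]:
    """Convenience wrapper: build the run design and fit it to (samples, voxels)."""
    design = build_design_matrix(events, data.shape[0], tr, hrf, motion)
    fit = fit_glm(design, data, tr, highpass_cutoff, ar1)
    return design, fit
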