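"""Multivariate noise normalization and cross-validated Mahalanobis distances.

The crossnobis estimator computes, for each condition pair (j, k), the mean
over ordered run pairs (m, n), m != n, of the inner product of the pattern
difference estimated in run m with the same difference estimated in run n,
divided by the voxel count P:

    d_jk = mean_{m != n}  (b_j^m - b_k^m) . (b_j^n - b_k^n) / P

Because the two difference estimates carry independent noise, the estimator
is unbiased: its expectation is the squared (noise-normalized) Euclidean
distance per voxel between the true patterns, and it is exactly zero in
expectation when the true patterns are equal — a ratio scale with an
interpretable zero.  Individual estimates may legitimately be negative.

Noise normalization whitens patterns by the inverse matrix square root of a
shrunk voxel covariance estimated from GLM residuals, down-weighting
directions of correlated noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model_rdms import PairMask

__all__ = [
    "BetaSet",
    "NoiseCov",
    "RDMData",
    "estimate_noise_cov",
    "whiten",
    "crossnobis_distances",
    "average_rdms",
]


@dataclass
class BetaSet:
    """Per-run condition patterns: (runs M, conditions K, voxels P)."""

    betas: np.ndarray
    condition_labels: tuple[str, ...]

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 3:
            raise ValueError("betas must be (runs, conditions, voxels)")
        if self.betas.shape[1] != len(self.condition_labels):
            raise ValueError("condition manifest does not match beta array")
        if not np.isfinite(self.betas).all():
            raise ValueError("betas contain non-finite values")

    @property
    def n_runs(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[2]


@dataclass
class NoiseCov:
    """Shrunk voxel-by-voxel noise covariance."""

    cov: np.ndarray
    shrinkage: float
    dof: int

    def __post_init__(self):
        c = np.asarray(self.cov, dtype=float)
        if not np.allclose(c, c.T):
            raise ValueError("covariance must be symmetric")
        self.cov = 0.5 * (c + c.T)

    def inv_sqrt(self) -> np.ndarray:
        """Symmetric inverse square root via eigendecomposition."""
        vals, vecs = np.linalg.eigh(self.cov)
        if vals.min() <= 0:
            raise np.linalg.LinAlgError(
                f"noise covariance not positive definite (min eig {vals.min():.3g})"
            )
        return (vecs / np.sqrt(vals)) @ vecs.T


@dataclass
class RDMData:
    """Crossnobis distances over a pair manifest.

    ``distances`` is the vector over upper-triangle pairs selected by
    ``pair_mask`` (i < j order).  Values are signed squared-Mahalanobis units
    per voxel; self-distances are never stored.
    """

    distances: np.ndarray
    pair_mask: PairMask
    n_runs: int

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.shape != (self.pair_mask.n_pairs,):
            raise ValueError("distance vector does not match pair manifest")

    def to_matrix(self) -> np.ndarray:
        """Square symmetric matrix, NaN outside the manifest, zero diagonal."""
        n = len(self.pair_mask.conditions)
        out = np.full((n, n), np.nan)
        i, j = self.pair_mask.pair_indices()
        out[i, j] = out[j, i] = self.distances
        np.fill_diagonal(out, 0.0)
        return out

    def subset(self, mask: PairMask) -> np.ndarray:
        """Distances over the intersection of the manifest with another mask."""
        i, j = self.pair_mask.pair_indices()
        keep = mask.indicator[i, j]
        return self.distances[keep]

    def to_pair_table(self) -> pd.DataFrame:
        labels = [c.label for c in self.pair_mask.conditions]
        i, j = self.pair_mask.pair_indices()
        return pd.DataFrame(
            {
                "condition_i": [labels[a] for a in i],
                "condition_j": [labels[b] for b in j],
                "distance": self.distances,
            }
        )


def estimate_noise_cov(
    residuals: Sequence[np.ndarray],
    dof: Sequence[int] | None = None,
    shrinkage: float | str = "auto",
) -> NoiseCov:
    """Pooled, diagonally-shrunk voxel covariance of per-run GLM residuals.

    Run-wise sample covariances (normalized by residual dof) are averaged and
    shrunk toward their diagonal: ``(1-lam) S + lam diag(S)``.  With
    ``shrinkage="auto"`` the off-diagonal shrinkage intensity follows the
    Ledoit-Wolf/Schafer-Strimmer analytic formula, guaranteeing a positive
    definite result while preserving voxel variances.
    """
    residuals = [np.asarray(r, dtype=float) for r in residuals]
    if any(r.ndim != 2 for r in residuals):
        raise ValueError("each residual array must be (samples, voxels)")
    p = residuals[0].shape[1]
    if dof is None:
        dof = [r.shape[0] - 1 for r in residuals]
    covs = []
    for r, d in zip(residuals, dof):
        if r.shape[0] < 2:
            raise ValueError("need at least 2 residual samples per run")
        rc = r - r.mean(axis=0)
        covs.append(rc.T @ rc / d)
    S = np.mean(covs, axis=0)
    zero_var = np.nonzero(np.diag(S) <= 0)[0]
    if zero_var.size:
        raise ValueError(f"zero-variance voxel(s) at indices {zero_var.tolist()}")

    if shrinkage == "auto":
        # variance of the off-diagonal covariance entries over pooled samples
        pooled = np.concatenate([r - r.mean(axis=0) for r in residuals], axis=0)
        n = pooled.shape[0]
        x2 = pooled**2
        var_s = (x2.T @ x2 / n - (pooled.T @ pooled / n) ** 2) * n / (n - 1) ** 2
        off = ~np.eye(p, dtype=bool)
        denom = (S[off] ** 2).sum()
        lam = 1.0 if denom == 0 else float(np.clip(var_s[off].sum() / denom, 0.0, 1.0))
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage must be in [0, 1]")
    shrunk = (1.0 - lam) * S + lam * np.diag(np.diag(S))
    return NoiseCov(shrunk, lam, int(np.sum(dof)))


def whiten(betas: BetaSet, cov: NoiseCov) -> BetaSet:
    """Right-multiply every pattern by the covariance inverse square root."""
    W = cov.inv_sqrt()
    return BetaSet(betas.betas @ W, betas.condition_labels)


def crossnobis_distances(betas: BetaSet, pair_mask: PairMask | None = None) -> RDMData:
    """Cross-validated squared Mahalanobis distance per voxel for each pair.

    Uses the identity  sum_{m != n} d_m . d_n = ||sum_m d_m||^2 - sum_m ||d_m||^2
    over run-wise pattern differences d_m, avoiding the explicit fold loop.
    """
    M, K, P = betas.betas.shape
    if M < 2:
        raise ValueError("crossnobis needs at least 2 runs")
    if pair_mask is None:
        pair_mask = _label_mask(betas.condition_labels, ~np.eye(K, dtype=bool))
    i, j = pair_mask.pair_indices()
    diffs = betas.betas[:, i, :] - betas.betas[:, j, :]  # (M, npairs, P)
    total = diffs.sum(axis=0)
    cross = (total**2).sum(axis=-1) - (diffs**2).sum(axis=-1).sum(axis=0)
    d = cross / (M * (M - 1) * P)
    return RDMData(d, pair_mask, M)


class _LabelCondition:
    """Minimal condition stand-in carrying only a label (for bare BetaSets)."""

    __slots__ = ("label",)

    def __init__(self, label: str):
        self.label = label


def _label_mask(labels: Sequence[str], indicator: np.ndarray) -> PairMask:
    return PairMask(tuple(_LabelCondition(l) for l in labels), indicator)


def average_rdms(rdms: Sequence[RDMData]) -> RDMData:
    """Elementwise mean of RDMs sharing one pair manifest."""
    if not rdms:
        raise ValueError("no RDMs to average")
    first = rdms[0]
    ref = [c.label for c in first.pair_mask.conditions]
    for r in rdms[1:]:
        if [c.label for c in r.pair_mask.conditions] != ref or not np.array_equal(
            r.pair_mask.indicator, first.pair_mask.indicator
        ):
            raise ValueError("pair manifests differ; cannot average")
    mean = np.mean([r.distances for r in rdms], axis=0)
    return RDMData(mean, first.pair_mask, first.n_runs)
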