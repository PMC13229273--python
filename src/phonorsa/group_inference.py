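"""Group-level statistics: tau-a model fits, gated two-step testing, behavior.

Model fit is Kendall's tau-a between a theoretical RDM and the empirical
distances over a pair subset, Fisher-z transformed per subject, then tested
against zero with a one-tailed one-sample t-test (negative fits are not
meaningful).  Differences between models use two-tailed paired t-tests.

The two-step procedure mirrors the conditional testing logic: the Shared
Phonemes model is tested in the combined within-stimulus distances of every
candidate cluster (Bonferroni over clusters); only clusters passing are
tested in the across-stimulus distances; only clusters passing that gate are
tested against the Sublexical and Lexical models across-stimulus, each
Bonferroni-corrected for the number of clusters reaching its step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .crossnobis import RDMData
from .model_rdms import ModelRDM, PairMask, partition_mask

__all__ = [
    "kendall_tau_a",
    "kendall_tau_a_many",
    "fisher_z",
    "one_sample_t",
    "paired_t",
    "model_fit_z",
    "TwoStepPlan",
    "run_two_step",
    "segment_position_contrast",
    "brain_behavior_corr",
    "classical_mds",
]


def kendall_tau_a(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall's tau-a: (concordant - discordant) / (n(n-1)/2).

    Pairs tied in either vector count as neither concordant nor discordant
    (they reduce the numerator only, unlike tau-b's denominator correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    i, j = np.triu_indices(n, 1)
    sx = np.sign(x[i] - x[j])
    sy = np.sign(y[i] - y[j])
    if not sx.any() and not sy.any():
        raise ValueError("all pairs tied in both vectors; tau-a undefined")
    return float((sx * sy).sum() / (n * (n - 1) / 2))


def kendall_tau_a_many(X: np.ndarray, y: np.ndarray, chunk: int = 512) -> np.ndarray:
    """tau-a of each row of X against a fixed vector y (vectorized)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.size
    if X.shape[1] != n:
        raise ValueError("row length must match y")
    i, j = np.triu_indices(n, 1)
    sy = np.sign(y[i] - y[j])
    if not sy.any():
        raise ValueError("all model pairs tied; tau-a direction undefined")
    denom = n * (n - 1) / 2
    out = np.empty(X.shape[0])
    for a in range(0, X.shape[0], chunk):
        sub = X[a : a + chunk]
        sx = np.sign(sub[:, i] - sub[:, j])
        out[a : a + chunk] = (sx * sy).sum(axis=1) / denom
    return out


def fisher_z(r: float | np.ndarray, eps: float = 1e-7) -> float | np.ndarray:
    """atanh transform; correlations at exactly +/-1 are clamped with a warning."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) >= 1.0):
        warnings.warn("correlation at +/-1 clamped before Fisher z", stacklevel=2)
        r_arr = np.clip(r_arr, -1.0 + eps, 1.0 - eps)
    out = np.arctanh(r_arr)
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


def one_sample_t(values: np.ndarray, tail: str = "one") -> tuple[float, int, float, float]:
    """One-sample t against zero; returns (t, df, p, d_z) with d_z = t/sqrt(n)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 values")
    sdv = v.std(ddof=1)
    if sdv == 0:
        raise ValueError("zero variance; t undefined")
    t = v.mean() / (sdv / np.sqrt(n))
    df = n - 1
    if tail == "one":
        p = float(sps.t.sf(t, df))
    elif tail == "two":
        p = float(2 * sps.t.sf(abs(t), df))
    else:
        raise ValueError("tail must be 'one' or 'two'")
    return float(t), df, p, float(t / np.sqrt(n))


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float, float]:
    """Two-tailed paired t-test via the one-sample t on differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, tail="two")


def model_fit_z(rdm: RDMData, model: ModelRDM, mask: PairMask | None = None) -> float:
    """Fisher-z Kendall tau-a fit of one subject's RDM to a model over a mask."""
    eval_mask = model.mask if mask is None else model.mask.intersect(mask)
    data = rdm.subset(eval_mask)
    pred = model.masked_vector(mask)
    if data.size < 3:
        raise ValueError("fewer than 3 pairs selected; fit is meaningless")
    return fisher_z(kendall_tau_a(data, pred))


@dataclass(frozen=True)
class TwoStepPlan:
    """Gated test sequence parameters."""

    alpha: float = 0.05
    within_relation: str = "within_type_any"
    across_relation: str = "across_type"


def _fit_row(z_values, cluster, step, model_name, partition, m):
    t, df, p, d_z = one_sample_t(z_values, tail="one")
    return dict(
        cluster=cluster, step=step, model=model_name, partition=partition,
        n=len(z_values), t=t, df=df, p=p, d_z=d_z, bonferroni_m=m,
        p_corrected=min(1.0, p * m), significant=False,
    )


def run_two_step(
    cluster_rdms: dict[object, list[RDMData]],
    models: dict[str, ModelRDM],
    conditions,
    plan: TwoStepPlan = TwoStepPlan(),
) -> pd.DataFrame:
    """Execute the conditional two-step model-testing procedure.

    ``cluster_rdms`` maps cluster id to one averaged RDM per subject (full
    pair manifest).  ``models`` must contain ``shared_phonemes``,
    ``sublexical`` and ``lexical``.  Returns one row per executed test with
    Bonferroni-corrected significance; gated tests that never ran are absent.
    """
    within = partition_mask(conditions, plan.within_relation)
    across = partition_mask(conditions, plan.across_relation)
    types = sorted({c.stimulus_type for c in conditions})
    rows: list[dict] = []

    def _test(clusters, model_name, mask, partition, step):
        m = len(clusters)
        passed = []
        for cl in clusters:
            z = [model_fit_z(r, models[model_name], mask) for r in cluster_rdms[cl]]
            row = _fit_row(z, cl, step, model_name, partition, m)
            row["significant"] = row["p_corrected"] < plan.alpha
            rows.append(row)
            if row["significant"]:
                passed.append(cl)
        return passed

    all_clusters = list(cluster_rdms)
    gate1 = _test(all_clusters, "shared_phonemes", within, "within", "1_within_shared")
    gate2 = _test(gate1, "shared_phonemes", across, "across", "2_across_shared")
    sub_pass = _test(gate2, "sublexical", across, "across", "3_across_sublexical")
    _test(gate2, "lexical", across, "across", "3_across_lexical")
    # per-type follow-up for clusters with across-stimulus sublexical structure
    for stype in types:
        mask_t = partition_mask(conditions, "within_type", stimulus_type=stype)
        _test(sub_pass, "sublexical", mask_t, f"within_{stype}", "4_per_type_sublexical")
    return pd.DataFrame(rows)


def segment_position_contrast(fits: np.ndarray) -> tuple[float, int, int, float]:
    """One-way repeated-measures ANOVA over phoneme position.

    ``fits`` is (subjects, positions).  Returns (F, df1, df2, p).
    """
    x = np.asarray(fits, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("fits must be (subjects >= 2, positions)")
    n, k = x.shape
    grand = x.mean()
    subj_means = x.mean(axis=1, keepdims=True)
    cond_means = x.mean(axis=0, keepdims=True)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    resid = x - subj_means - cond_means + grand
    ss_err = (resid**2).sum()
    df1, df2 = k - 1, (n - 1) * (k - 1)
    tol = 1e-12 * max(1.0, float((x**2).sum()))
    if ss_cond <= tol:
        return 0.0, df1, df2, 1.0
    if ss_err <= tol:
        return np.inf, df1, df2, 0.0
    F = (ss_cond / df1) / (ss_err / df2)
    return float(F), df1, df2, float(sps.f.sf(F, df1, df2))


def brain_behavior_corr(fits: np.ndarray, scores: np.ndarray) -> dict:
    """Pearson correlation of per-subject model fits with reading scores.

    One-tailed p (positive direction) from t = r sqrt(n-2) / sqrt(1-r^2).
    """
    x = np.asarray(fits, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("need matched fit/score vectors with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in inputs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in fits or scores")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    if abs(r) >= 1.0:
        p = 0.0 if r > 0 else 1.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
        p = float(sps.t.sf(t, n - 2))
    return {"r": r, "n": n, "df": n - 2, "p_one_tailed": p}


def classical_mds(rdm: np.ndarray, dims: int = 2) -> np.ndarray:
    """Torgerson classical multidimensional scaling of a distance matrix.

    Negative input distances (legitimate for crossnobis estimates) are
    clamped to zero with a warning; coordinates are eigenvectors of the
    double-centered squared-distance matrix scaled by the root eigenvalues,
    with nonpositive-eigenvalue dimensions dropped.
    """
    D = np.asarray(rdm, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("rdm must be a symmetric square matrix")
    if (D < 0).any():
        warnings.warn("negative distances clamped to 0 for MDS", stacklevel=2)
        D = np.clip(D, 0.0, None)
    n = D.shape[0]
    if n == 1:
        return np.zeros((1, dims))
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = min(dims, int((vals > 1e-12).sum()))
    if keep < dims:
        warnings.warn(
            f"only {keep} positive-eigenvalue dimensions available", stacklevel=2
        )
    coords = vecs[:, :keep] * np.sqrt(vals[:keep])
    if keep < dims:
        coords = np.pad(coords, ((0, 0), (0, dims - keep)))
    return coords
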