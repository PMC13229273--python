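"""Volumetric searchlight mapping, conjunction group maps, cluster inference.

A searchlight slides a sphere (default radius 3 voxels = 9 mm at 3 mm
isotropic) over every in-mask voxel and computes a multivariate statistic
from the voxels it contains: the mean crossnobis distance over a pair subset
(information maps) or the Fisher-z Kendall tau-a fit of the local RDM to a
theoretical model (direct model-fit maps).

Two computational engines produce identical quantities under their shared
assumptions:

* ``"diagonal"`` (default) — univariate noise normalization (each voxel
  scaled by its pooled residual standard deviation).  Per-voxel crossnobis
  contributions are additive over the sphere, so the whole map reduces to a
  sparse neighborhood aggregation; this is exact and fast.
* ``"sphere"`` — full multivariate noise normalization per searchlight: the
  sphere's shrunk residual covariance whitens the local patterns before the
  distance computation.  This is the reference path, O(centers) eigendecompositions.

Group inference: per-center one-sample t over subjects for each stimulus
type, a minimum-statistic conjunction thresholded at a one-tailed peak p,
26-connected cluster formation, cluster-level p-values from a sign-flip
permutation max-cluster-size null, and Benjamini-Hochberg FDR over clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .crossnobis import BetaSet, NoiseCov, crossnobis_distances, estimate_noise_cov, whiten
from .group_inference import fisher_z, kendall_tau_a_many
from .model_rdms import ModelRDM, PairMask, partition_mask
from .synthetic_fmri import VolumeGeometry

__all__ = [
    "SearchlightSpec",
    "Searchlight",
    "StatMap",
    "ClusterTable",
    "within_type_distance_maps",
    "conjunction_group_map",
    "model_fit_searchlight",
    "cluster_average_rdms",
]

CONNECTIVITY = np.ones((3, 3, 3), dtype=bool)  # 26-neighborhood


@dataclass(frozen=True)
class SearchlightSpec:
    radius: float = 3.0  # voxels (9 mm at 3 mm isotropic)
    min_voxels: int = 2
    normalization: str = "diagonal"  # diagonal | sphere | none
    shrinkage: float | str = "auto"

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.min_voxels < 2:
            raise ValueError("min_voxels must be >= 2")
        if self.normalization not in ("diagonal", "sphere", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


class Searchlight:
    """Precomputed sphere membership over a masked grid.

    Centers are all in-mask voxels whose sphere contains at least
    ``min_voxels`` in-mask members; skipped centers are recorded.
    """

    def __init__(self, geometry: VolumeGeometry, spec: SearchlightSpec = SearchlightSpec()):
        self.geometry = geometry
        self.spec = spec
        coords = geometry.mask_indices()  # (nvox, 3)
        self.coords = coords
        nvox = coords.shape[0]
        flat_of_voxel = -np.ones(geometry.shape, dtype=np.int64)
        flat_of_voxel[tuple(coords.T)] = np.arange(nvox)
        self._flat_of_voxel = flat_of_voxel

        r = spec.radius
        ri = int(np.floor(r))
        offs = np.array(
            [
                (i, j, k)
                for i in range(-ri, ri + 1)
                for j in range(-ri, ri + 1)
                for k in range(-ri, ri + 1)
                if i * i + j * j + k * k <= r * r
            ]
        )
        rows, cols = [], []
        center_ids, skipped = [], []
        shape = np.array(geometry.shape)
        for v in range(nvox):
            nb = coords[v] + offs
            ok = np.all((nb >= 0) & (nb < shape), axis=1)
            members = flat_of_voxel[tuple(nb[ok].T)]
            members = members[members >= 0]
            if members.size < spec.min_voxels:
                skipped.append(v)
                continue
            rows.append(np.full(members.size, len(center_ids)))
            cols.append(members)
            center_ids.append(v)
        self.center_ids = np.array(center_ids, dtype=np.int64)
        self.skipped = np.array(skipped, dtype=np.int64)
        if cols:
            data = np.ones(sum(len(c) for c in cols))
            ij = (np.concatenate(rows), np.concatenate(cols))
        else:
            data, ij = np.empty(0), (np.empty(0, int), np.empty(0, int))
        self.membership = sparse.csr_matrix(
            (data, ij), shape=(len(center_ids), nvox)
        )
        self.counts = np.asarray(self.membership.sum(axis=1)).ravel()

    @property
    def n_centers(self) -> int:
        return self.center_ids.size

    def sphere_indices(self, center: tuple[int, int, int]) -> np.ndarray:
        """In-mask voxel indices of the sphere at a voxel-coordinate center."""
        v = self._flat_of_voxel[tuple(center)]
        if v < 0:
            raise ValueError(f"center {center} is outside the analysis mask")
        pos = np.searchsorted(self.center_ids, v)
        if pos >= self.center_ids.size or self.center_ids[pos] != v:
            raise ValueError(f"center {center} was skipped (sphere below minimum)")
        row = self.membership.getrow(pos)
        return row.indices

    def map_to_volume(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        vol = np.full(self.geometry.shape, fill, dtype=float)
        vol[tuple(self.coords[self.center_ids].T)] = values
        return vol


@dataclass
class StatMap:
    values: np.ndarray  # per center
    searchlight: Searchlight
    label: str

    def to_volume(self) -> np.ndarray:
        return self.searchlight.map_to_volume(self.values)


@dataclass
class ClusterTable:
    table: pd.DataFrame
    labels: np.ndarray  # 3D int volume; 0 = background

    def member_centers(self, cluster_id: int, sl: Searchlight) -> np.ndarray:
        """Indices (into the center list) of a cluster's member voxels."""
        coords = sl.coords[sl.center_ids]
        in_cluster = self.labels[tuple(coords.T)] == cluster_id
        return np.nonzero(in_cluster)[0]


# ---------------------------------------------------------------------------
# per-subject maps


def _diagonal_whiten(betas: BetaSet, residuals, normalization: str) -> BetaSet:
    if normalization == "none":
        return betas
    var = np.mean([np.var(r, axis=0, ddof=1) for r in residuals], axis=0)
    if (var <= 0).any():
        raise ValueError("zero-variance voxel in residuals")
    return BetaSet(betas.betas / np.sqrt(var), betas.condition_labels)


def _pair_contributions(betas: BetaSet, pair_mask: PairMask) -> np.ndarray:
    """Per-voxel crossnobis numerators, (npairs, nvox); divide by M(M-1)P later."""
    i, j = pair_mask.pair_indices()
    diffs = betas.betas[:, i, :] - betas.betas[:, j, :]
    total = diffs.sum(axis=0)
    return total**2 - (diffs**2).sum(axis=0)


def subject_pair_distances(
    sl: Searchlight,
    betas: BetaSet,
    residuals,
    pair_mask: PairMask,
) -> np.ndarray:
    """Crossnobis RDM at every searchlight center: (n_centers, n_pairs)."""
    M = betas.n_runs
    if sl.spec.normalization in ("diagonal", "none"):
        wb = _diagonal_whiten(betas, residuals, sl.spec.normalization)
        contrib = _pair_contributions(wb, pair_mask)  # (npairs, nvox)
        agg = sl.membership @ contrib.T  # (ncenters, npairs)
        return agg / (M * (M - 1) * sl.counts[:, None])
    out = np.empty((sl.n_centers, pair_mask.n_pairs))
    for c in range(sl.n_centers):
        idx = sl.membership.indices[
            sl.membership.indptr[c] : sl.membership.indptr[c + 1]
        ]
        local = BetaSet(betas.betas[:, :, idx], betas.condition_labels)
        cov = estimate_noise_cov([r[:, idx] for r in residuals],
                                 shrinkage=sl.spec.shrinkage)
        rdm = crossnobis_distances(whiten(local, cov), pair_mask)
        out[c] = rdm.distances
    return out


def within_type_distance_maps(
    sl: Searchlight,
    betas: BetaSet,
    residuals,
    conditions,
) -> dict[str, StatMap]:
    """Mean within-stimulus-type crossnobis distance per center, per type."""
    types = sorted({c.stimulus_type for c in conditions})
    M = betas.n_runs
    if sl.spec.normalization in ("diagonal", "none"):
        wb = _diagonal_whiten(betas, residuals, sl.spec.normalization)
        maps = {}
        for stype in types:
            mask = partition_mask(conditions, "within_type", stimulus_type=stype)
            contrib = _pair_contributions(wb, mask).mean(axis=0)  # (nvox,)
            vals = (sl.membership @ contrib) / (M * (M - 1) * sl.counts)
            maps[stype] = StatMap(vals, sl, f"within_{stype}_distance")
        return maps
    masks = {
        stype: partition_mask(conditions, "within_type", stimulus_type=stype)
        for stype in types
    }
    union = PairMask(
        masks[types[0]].conditions,
        np.logical_or.reduce([m.indicator for m in masks.values()]),
    )
    dists = subject_pair_distances(sl, betas, residuals, union)
    ui, uj = union.pair_indices()
    maps = {}
    for stype in types:
        sel = masks[stype].indicator[ui, uj]
        maps[stype] = StatMap(
            dists[:, sel].mean(axis=1), sl, f"within_{stype}_distance"
        )
    return maps


def model_fit_searchlight(
    sl: Searchlight,
    betas: BetaSet,
    residuals,
    model: ModelRDM,
    mask: PairMask | None = None,
) -> StatMap:
    """Fisher-z tau-a fit of the local RDM to a model at every center."""
    eval_mask = model.mask if mask is None else model.mask.intersect(mask)
    if eval_mask.n_pairs < 3:
        raise ValueError("fewer than 3 masked pairs per center")
    pred = model.masked_vector(mask)
    dists = subject_pair_distances(sl, betas, residuals, eval_mask)
    taus = kendall_tau_a_many(dists, pred)
    return StatMap(fisher_z(taus), sl, f"fit_{model.name}")


# ---------------------------------------------------------------------------
# group-level conjunction and clusters


def _t_maps(stack: np.ndarray) -> np.ndarray:
    """One-sample t over axis 0; zero where the across-subject sd vanishes."""
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def _label_clusters(supra_vol: np.ndarray) -> tuple[np.ndarray, int]:
    return ndimage.label(supra_vol, structure=CONNECTIVITY)


def conjunction_group_map(
    sl: Searchlight,
    maps_by_type: dict[str, np.ndarray],
    peak_p: float = 0.001,
    cluster_q: float = 0.05,
    n_permutations: int = 10000,
    rng: np.random.Generator | int = 0,
) -> tuple[StatMap, ClusterTable]:
    """Conjunction inference over per-subject maps of both stimulus types.

    ``maps_by_type[stype]`` is (n_subjects, n_centers).  The conjunction
    statistic is the minimum of the per-type one-sample t values; a center is
    suprathreshold only if every type exceeds the one-tailed peak-p t
    threshold.  Cluster p-values come from a sign-flip permutation null of
    the maximum cluster size (2^n or ``n_permutations`` flips, whichever is
    smaller), followed by BH-FDR across clusters at ``cluster_q``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    stacks = list(maps_by_type.values())
    n_sub = stacks[0].shape[0]
    if any(s.shape != stacks[0].shape for s in stacks):
        raise ValueError("per-type map stacks differ in shape")
    if n_sub < 3:
        raise ValueError("need at least 3 subjects")
    if n_sub < 8:
        import warnings

        warnings.warn(
            "fewer than 8 subjects: sign-flip permutation resolution is coarse",
            stacklevel=2,
        )
    df = n_sub - 1
    t_thresh = float(sps.t.isf(peak_p, df))
    t_by_type = np.array([_t_maps(s) for s in stacks])  # (ntype, ncenters)
    conj = t_by_type.min(axis=0)
    supra = np.all(t_by_type > t_thresh, axis=0)

    conj_map = StatMap(conj, sl, "conjunction_min_t")
    empty = ClusterTable(
        pd.DataFrame(
            columns=[
                "cluster_id", "size", "peak_stat", "peak_voxel", "p_cluster",
                "q_fdr", "significant",
            ]
        ),
        np.zeros(sl.geometry.shape, dtype=int),
    )
    if not supra.any():
        return conj_map, empty

    supra_vol = sl.map_to_volume(supra.astype(float), fill=0.0) > 0
    labels, n_clusters = _label_clusters(supra_vol)
    center_coords = sl.coords[sl.center_ids]
    center_labels = labels[tuple(center_coords.T)]
    sizes = np.array(
        [(center_labels == c).sum() for c in range(1, n_clusters + 1)]
    )

    n_perm = min(int(n_permutations), 2**n_sub)
    null_max = _max_cluster_null(sl, stacks, t_thresh, n_perm, rng)
    p_cluster = np.array(
        [(1 + np.sum(null_max >= s)) / (n_perm + 1) for s in sizes]
    )
    reject, q_vals, *_ = multipletests(p_cluster, alpha=cluster_q, method="fdr_bh")

    rows = []
    for c in range(n_clusters):
        members = center_labels == c + 1
        peak_idx = np.argmax(np.where(members, conj, -np.inf))
        rows.append(
            dict(
                cluster_id=c + 1,
                size=int(sizes[c]),
                peak_stat=float(conj[peak_idx]),
                peak_voxel=tuple(int(x) for x in center_coords[peak_idx]),
                p_cluster=float(p_cluster[c]),
                q_fdr=float(q_vals[c]),
                significant=bool(reject[c]),
            )
        )
    table = pd.DataFrame(rows).sort_values("size", ascending=False).reset_index(drop=True)
    return conj_map, ClusterTable(table, labels)


def _max_cluster_null(
    sl: Searchlight,
    stacks: list[np.ndarray],
    t_thresh: float,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sign-flip null distribution of the maximum conjunction cluster size."""
    n_sub, n_centers = stacks[0].shape
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    msq = [np.mean(s**2, axis=0) for s in stacks]  # invariant under flips
    null_max = np.zeros(n_perm, dtype=int)
    vol = np.zeros(sl.geometry.shape, dtype=bool)
    coords = tuple(sl.coords[sl.center_ids].T)
    for p in range(n_perm):
        supra = np.ones(n_centers, dtype=bool)
        for s, m2 in zip(stacks, msq):
            mean = signs[p] @ s / n_sub
            var = np.maximum(m2 - mean**2, 0.0) * n_sub / (n_sub - 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(var > 0, mean / np.sqrt(var / n_sub), 0.0)
            supra &= t > t_thresh
            if not supra.any():
                break
        if not supra.any():
            continue
        vol[:] = False
        vol[coords] = supra
        labels, nc = _label_clusters(vol)
        if nc:
            null_max[p] = np.bincount(labels.ravel())[1:].max()
    return null_max


def cluster_average_rdms(
    sl: Searchlight,
    clusters: ClusterTable,
    subjects_betas: list[BetaSet],
    subjects_residuals: list,
    pair_mask: PairMask,
    significant_only: bool = True,
):
    """Per-cluster, per-subject RDMs averaged over member searchlight centers.

    Returns ``{cluster_id: [RDMData per subject]}`` ready for the two-step
    group procedure.
    """
    from .crossnobis import RDMData

    table = clusters.table
    if significant_only:
        table = table[table["significant"]]
    out: dict[int, list] = {}
    member_idx = {
        int(row.cluster_id): clusters.member_centers(int(row.cluster_id), sl)
        for row in table.itertuples()
    }
    for betas, resid in zip(subjects_betas, subjects_residuals):
        dists = subject_pair_distances(sl, betas, resid, pair_mask)
        for cid, members in member_idx.items():
            rdm = RDMData(dists[members].mean(axis=0), pair_mask, betas.n_runs)
            out.setdefault(cid, []).append(rdm)
    return out
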