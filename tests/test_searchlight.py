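"""Sphere extraction, distance/model-fit maps, and cluster-level inference."""

import numpy as np
import pandas as pd
import pytest

from phonorsa import stimulus_design as sd
from phonorsa import synthetic_fmri as sf
from phonorsa.crossnobis import BetaSet
from phonorsa.model_rdms import (
    PairMask,
    partition_mask,
    shared_phonemes_model,
)
from phonorsa.searchlight import (
    ClusterTable,
    Searchlight,
    SearchlightSpec,
    cluster_average_rdms,
    conjunction_group_map,
    model_fit_searchlight,
    subject_pair_distances,
    within_type_distance_maps,
)


class TestSphereIndices:
    def test_tiny_radius_returns_center_only(self, small_geometry):
        # radius below 1 voxel: min_voxels=2 can never be met -> all skipped;
        # relax the minimum via a direct neighborhood check instead
        sl = Searchlight(small_geometry, SearchlightSpec(radius=0.5, min_voxels=2))
        assert sl.n_centers == 0
        assert sl.skipped.size == small_geometry.n_voxels

    def test_count_matches_brute_force(self, small_geometry):
        r = 2.0
        sl = Searchlight(small_geometry, SearchlightSpec(radius=r))
        center = (5, 5, 5)
        got = set(map(tuple, sl.coords[sl.sphere_indices(center)]))
        brute = {
            (x, y, z)
            for x in range(10) for y in range(10) for z in range(10)
            if (x - 5) ** 2 + (y - 5) ** 2 + (z - 5) ** 2 <= r**2
        }
        assert got == brute

    def test_mask_edge_respected(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[:3] = True
        geom = sf.VolumeGeometry(shape=(6, 6, 6), mask=mask)
        sl = Searchlight(geom, SearchlightSpec(radius=2.0))
        members = sl.coords[sl.sphere_indices((2, 3, 3))]
        assert (members[:, 0] < 3).all()

    def test_out_of_mask_center_rejected(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[:3] = True
        geom = sf.VolumeGeometry(shape=(6, 6, 6), mask=mask)
        sl = Searchlight(geom, SearchlightSpec(radius=2.0))
        with pytest.raises(ValueError):
            sl.sphere_indices((5, 5, 5))


@pytest.fixture(scope="module")
def planted_subject(conditions):
    geom = sf.VolumeGeometry(shape=(10, 10, 10))
    eff = sf.EffectSpec(roi_center=(5, 5, 5), roi_radius=2.0)
    subs = sf.generate_cohort(
        sd.ParadigmSpec(), geom, eff,
        sf.NoiseSpec(beta_noise_sd=1.0), sf.CohortSpec(3), seed=17,
    )
    return geom, eff, subs[0]


class TestEngines:
    def test_sphere_engine_with_full_shrinkage_equals_diagonal_engine(
        self, planted_subject, conditions
    ):
        """lambda=1 sphere whitening shrinks to the per-voxel variances, so
        both engines must agree to numerical precision."""
        geom, _, rec = planted_subject
        mask = partition_mask(conditions, "across_type")
        fast = Searchlight(geom, SearchlightSpec(radius=1.5, normalization="diagonal"))
        slow = Searchlight(
            geom, SearchlightSpec(radius=1.5, normalization="sphere", shrinkage=1.0)
        )
        d_fast = subject_pair_distances(fast, rec.betas, rec.residuals, mask)
        d_slow = subject_pair_distances(slow, rec.betas, rec.residuals, mask)
        assert np.allclose(d_fast, d_slow, atol=1e-10)

    def test_full_multivariate_whitening_runs(self, planted_subject, conditions):
        geom, _, rec = planted_subject
        mask = partition_mask(conditions, "across_type")
        sl = Searchlight(
            geom, SearchlightSpec(radius=1.5, normalization="sphere", shrinkage="auto")
        )
        d = subject_pair_distances(sl, rec.betas, rec.residuals, mask)
        assert d.shape == (sl.n_centers, mask.n_pairs)
        assert np.isfinite(d).all()


class TestDistanceMaps:
    def test_signal_localized_to_roi(self, planted_subject, conditions):
        geom, eff, rec = planted_subject
        sl = Searchlight(geom, SearchlightSpec(radius=2.0))
        maps = within_type_distance_maps(sl, rec.betas, rec.residuals, conditions)
        assert set(maps) == {"visual_speech", "auditory_speech"}
        vol = maps["visual_speech"].to_volume()
        roi_val = vol[eff.roi_center]
        corner = vol[2, 2, 2]
        assert roi_val > 10 * abs(corner)

    def test_both_type_maps_share_centers(self, planted_subject, conditions):
        geom, _, rec = planted_subject
        sl = Searchlight(geom, SearchlightSpec(radius=2.0))
        maps = within_type_distance_maps(sl, rec.betas, rec.residuals, conditions)
        assert all(m.values.shape == (sl.n_centers,) for m in maps.values())

    def test_signal_free_map_mean_near_zero(self, conditions, rng):
        geom = sf.VolumeGeometry(shape=(8, 8, 8))
        sl = Searchlight(geom, SearchlightSpec(radius=2.0))
        means = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            betas = BetaSet(
                r.standard_normal((4, 32, geom.n_voxels)),
                tuple(c.label for c in conditions),
            )
            resid = [r.standard_normal((40, geom.n_voxels)) for _ in range(4)]
            maps = within_type_distance_maps(sl, betas, resid, conditions)
            means.append(maps["visual_speech"].values.mean())
        assert abs(np.mean(means)) < 0.01


class TestModelFitSearchlight:
    def test_exact_model_geometry_reaches_tie_adjusted_maximum(self, conditions):
        """Noise-free patterns whose squared distances are exactly affine in
        the model reach the maximum tau-a the model's ties allow.

        (With tied model predictions tau-a cannot reach 1: tied pairs stay in
        the n(n-1)/2 denominator.)  The embedding places a one-hot code of
        each positional phoneme on 8 voxels, so squared pattern distance is
        exactly 2 x (number of differing positions).
        """
        geom = sf.VolumeGeometry(shape=(5, 5, 5))
        phonemes_by_pos = [sd.INITIALS, sd.VOWELS, sd.FINALS]
        dims = []
        offset = 0
        for inv in phonemes_by_pos:
            dims.append({p: offset + k for k, p in enumerate(inv)})
            offset += len(inv)
        pat = np.zeros((32, geom.n_voxels))
        for k, cond in enumerate(conditions):
            for pos, label in enumerate(cond.word.labels):
                pat[k, dims[pos][label]] = 1.0
        betas = BetaSet(
            np.repeat(pat[None], 2, axis=0), tuple(c.label for c in conditions)
        )
        resid = [np.random.default_rng(s).standard_normal((20, geom.n_voxels))
                 for s in range(2)]
        sl = Searchlight(
            geom, SearchlightSpec(radius=4.5, normalization="none")
        )
        model = shared_phonemes_model(conditions)
        across = partition_mask(conditions, "across_type")
        fit = model_fit_searchlight(sl, betas, resid, model, across)
        # the sphere at the exact grid center covers the whole volume
        center_pos = np.where(
            (sl.coords[sl.center_ids] == (2, 2, 2)).all(axis=1)
        )[0][0]
        pred = model.masked_vector(across)
        i, j = np.triu_indices(pred.size, 1)
        sy = np.sign(pred[i] - pred[j])
        tau_max = (sy != 0).sum() / sy.size
        assert np.tanh(fit.values[center_pos]) == pytest.approx(tau_max, abs=1e-12)

    def test_constant_model_rejected(self, planted_subject, conditions):
        geom, _, rec = planted_subject
        sl = Searchlight(geom, SearchlightSpec(radius=2.0))
        model = shared_phonemes_model(conditions)
        const = type(model)(
            "const", model.conditions, np.zeros_like(model.predictions), model.mask
        )
        with pytest.raises(ValueError, match="tied"):
            model_fit_searchlight(sl, rec.betas, rec.residuals, const)


class TestConjunctionInference:
    def test_single_suprathreshold_voxel_single_cluster(self, small_searchlight):
        sl = small_searchlight
        n_sub, n_centers = 10, sl.n_centers
        rng = np.random.default_rng(0)
        base = {
            "a": rng.standard_normal((n_sub, n_centers)) * 0.01,
            "b": rng.standard_normal((n_sub, n_centers)) * 0.01,
        }
        hot = n_centers // 2
        for stack in base.values():
            stack[:, hot] += 5.0
        _, clusters = conjunction_group_map(sl, base, n_permutations=200, rng=1)
        assert len(clusters.table) == 1
        assert clusters.table.iloc[0]["size"] == 1

    def test_corner_touching_voxels_join_one_cluster(self, small_searchlight):
        """26-connectivity: two suprathreshold voxels sharing only a corner."""
        sl = small_searchlight
        coords = sl.coords[sl.center_ids]
        a = np.where((coords == (4, 4, 4)).all(axis=1))[0][0]
        b = np.where((coords == (5, 5, 5)).all(axis=1))[0][0]
        rng = np.random.default_rng(3)
        stacks = {"x": rng.standard_normal((10, sl.n_centers)) * 0.01}
        stacks["x"][:, [a, b]] += 5.0
        _, clusters = conjunction_group_map(sl, stacks, n_permutations=200, rng=2)
        # the cluster peaking at (4,4,4) must contain both corner-joined voxels
        row = clusters.table[clusters.table["peak_voxel"] == (4, 4, 4)]
        assert len(row) == 1 and row.iloc[0]["size"] == 2

    def test_conjunction_requires_both_types(self, small_searchlight):
        sl = small_searchlight
        rng = np.random.default_rng(5)
        a = rng.standard_normal((10, sl.n_centers)) * 0.1
        b = rng.standard_normal((10, sl.n_centers)) * 0.1
        a[:, 7] += 5.0  # only one type carries signal
        _, clusters = conjunction_group_map(
            sl, {"a": a, "b": b}, n_permutations=100, rng=3
        )
        assert len(clusters.table) == 0

    def test_too_few_subjects_rejected(self, small_searchlight):
        with pytest.raises(ValueError):
            conjunction_group_map(
                small_searchlight,
                {"a": np.zeros((2, small_searchlight.n_centers))},
            )

    def test_planted_cohort_recovers_roi_cluster(self, conditions):
        geom = sf.VolumeGeometry(shape=(12, 12, 12))
        eff = sf.EffectSpec(roi_center=(6, 6, 6), roi_radius=3.0)
        subs = sf.generate_cohort(
            sd.ParadigmSpec(), geom, eff, sf.NoiseSpec(), sf.CohortSpec(12),
            seed=23,
        )
        sl = Searchlight(geom, SearchlightSpec())
        stacks = {t: [] for t in ("visual_speech", "auditory_speech")}
        for s in subs:
            maps = within_type_distance_maps(sl, s.betas, s.residuals, conditions)
            for t in stacks:
                stacks[t].append(maps[t].values)
        stacks = {t: np.stack(v) for t, v in stacks.items()}
        _, clusters = conjunction_group_map(sl, stacks, n_permutations=500, rng=4)
        sig = clusters.table[clusters.table["significant"]]
        assert len(sig) >= 1
        peak = sig.iloc[0]["peak_voxel"]
        assert np.linalg.norm(np.array(peak) - np.array(eff.roi_center)) <= 4.0

    def test_cluster_rdm_averaging(self, conditions):
        geom = sf.VolumeGeometry(shape=(8, 8, 8))
        sl = Searchlight(geom, SearchlightSpec(radius=1.5))
        labels_vol = np.zeros(geom.shape, dtype=int)
        labels_vol[3:5, 3:5, 3:5] = 1
        table = pd.DataFrame(
            [dict(cluster_id=1, size=8, peak_stat=5.0, peak_voxel=(3, 3, 3),
                  p_cluster=0.001, q_fdr=0.001, significant=True)]
        )
        clusters = ClusterTable(table, labels_vol)
        rng = np.random.default_rng(9)
        betas = [
            BetaSet(rng.standard_normal((2, 32, geom.n_voxels)),
                    tuple(c.label for c in conditions))
            for _ in range(3)
        ]
        resid = [[rng.standard_normal((30, geom.n_voxels)) for _ in range(2)]
                 for _ in range(3)]
        full = PairMask(tuple(conditions), ~np.eye(32, dtype=bool))
        out = cluster_average_rdms(sl, clusters, betas, resid, full)
        assert set(out) == {1}
        assert len(out[1]) == 3
        # averaging over member spheres equals the mean of per-center RDMs
        members = clusters.member_centers(1, sl)
        d = subject_pair_distances(sl, betas[0], resid[0], full)
        assert np.allclose(out[1][0].distances, d[members].mean(axis=0))


class TestPermutationOrderInvariance:
    def test_maps_independent_of_subject_order(self, small_searchlight):
        sl = small_searchlight
        rng = np.random.default_rng(31)
        stack = rng.standard_normal((8, sl.n_centers))
        m1, _ = conjunction_group_map(sl, {"a": stack}, n_permutations=64, rng=7)
        m2, _ = conjunction_group_map(sl, {"a": stack.copy()}, n_permutations=64, rng=7)
        assert np.array_equal(m1.values, m2.values)
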