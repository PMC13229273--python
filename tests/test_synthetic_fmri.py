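"""Planted-pattern construction, BOLD simulation, and cohort generation."""

import numpy as np
import pytest

from phonorsa import stimulus_design as sd
from phonorsa import synthetic_fmri as sf
from phonorsa.first_level_glm import HRFParams, double_gamma_hrf
from phonorsa.group_inference import kendall_tau_a
from phonorsa.model_rdms import (
    lexical_model,
    partition_mask,
    shared_phonemes_model,
    sublexical_model,
)


@pytest.fixture(scope="module")
def geom():
    return sf.VolumeGeometry(shape=(12, 12, 12))


@pytest.fixture(scope="module")
def effect():
    return sf.EffectSpec(roi_center=(6, 6, 6), roi_radius=3.0)


def _true_sq_distances(patterns, roi_in_mask=None):
    """Squared Euclidean distances between condition patterns (per pair)."""
    K = patterns.shape[0]
    i, j = np.triu_indices(K, 1)
    d = patterns[i] - patterns[j]
    return (d**2).sum(axis=1)


class TestPlantedPatterns:
    def test_zero_weights_zero_patterns(self, geom, conditions):
        eff = sf.EffectSpec(
            roi_center=(6, 6, 6), w_shared_phon=0, w_modality_phon=0,
            w_lexical=0, w_form=0,
        )
        pat = sf.plant_condition_patterns(geom, conditions, eff, 0)
        assert not pat.any()

    def test_zero_outside_roi(self, geom, conditions, effect):
        pat = sf.plant_condition_patterns(geom, conditions, effect, 0)
        roi = geom.sphere_mask(effect.roi_center, effect.roi_radius)[geom.mask]
        assert not pat[:, ~roi].any()
        assert pat[:, roi].any()

    def test_same_word_across_modality_distance_zero(self, geom, conditions):
        # shared-phoneme component only: construction is identical across types
        eff = sf.EffectSpec(
            roi_center=(6, 6, 6), w_shared_phon=0.5, w_modality_phon=0,
            w_lexical=0, w_form=0,
        )
        pat = sf.plant_condition_patterns(geom, conditions, eff, 3)
        labels = [c.label for c in conditions]
        i = labels.index("beam_visual_speech_A")
        j = labels.index("beam_auditory_speech_B")
        assert np.allclose(pat[i], pat[j])

    def test_expected_squared_distance_matches_analytic(self, conditions):
        """E||p_i - p_j||^2 = 2 w^2 (3 - shared) * n_roi under the basis draw.

        Monte-Carlo over 1,000 independent basis draws on a small ROI.
        """
        geom = sf.VolumeGeometry(shape=(6, 6, 6))
        w = 0.4
        eff = sf.EffectSpec(
            roi_center=(3, 3, 3), roi_radius=2.0, w_shared_phon=w,
            w_modality_phon=0, w_lexical=0, w_form=0,
        )
        n_roi = int(geom.sphere_mask(eff.roi_center, eff.roi_radius).sum())
        conds = conditions[:: 4]  # one condition per word (visual A)
        acc = np.zeros(len(conds) * (len(conds) - 1) // 2)
        n_rep = 1000
        rng = np.random.default_rng(7)
        for _ in range(n_rep):
            pat = sf.plant_condition_patterns(geom, conds, eff, rng)
            acc += _true_sq_distances(pat)
        mc = acc / n_rep
        i, j = np.triu_indices(len(conds), 1)
        shared = np.array(
            [sd.shared_phoneme_count(conds[a].word, conds[b].word)
             for a, b in zip(i, j)]
        )
        expected = 2 * w**2 * (3 - shared) * n_roi
        assert np.allclose(mc, expected, rtol=0.12)

    def test_true_rdm_matches_shared_phonemes_model_exactly(self, geom, conditions):
        """Expected noiseless across-type geometry is exactly proportional to
        the Shared Phonemes model, so tau-a reaches the tie-adjusted ceiling.

        (tau-a keeps tied pairs in its denominator, so 1.0 itself is not
        attainable for a model with tied predictions.)
        """
        model = shared_phonemes_model(conditions)
        across = partition_mask(conditions, "across_type")
        i, j = model.mask.intersect(across).pair_indices()
        shared = np.array(
            [sd.shared_phoneme_count(conditions[a].word, conditions[b].word)
             for a, b in zip(i, j)]
        )
        expected_d = 2 * 0.3**2 * (3 - shared)  # analytic expectation, any ROI size
        pred = model.predictions[i, j]
        assert np.allclose(expected_d, 2 * 0.3**2 * pred)  # exact proportionality
        a, b = np.triu_indices(pred.size, 1)
        sy = np.sign(pred[a] - pred[b])
        tau_max = (sy != 0).sum() / sy.size
        assert kendall_tau_a(expected_d, pred) == pytest.approx(tau_max, abs=1e-12)

    def test_lexical_only_dissociation(self, geom, conditions):
        """Lexical-only planting: tau=1 vs Lexical, ~0 vs Sublexical (across)."""
        eff = sf.EffectSpec(
            roi_center=(6, 6, 6), w_shared_phon=0, w_modality_phon=0,
            w_lexical=0.5, w_form=0,
        )
        across = partition_mask(conditions, "across_type")
        lex = lexical_model(conditions)
        sub = sublexical_model(conditions)
        # average the empirical geometry over many draws -> expectation
        acc = None
        rng = np.random.default_rng(11)
        for _ in range(200):
            pat = sf.plant_condition_patterns(geom, conditions, eff, rng)
            d = _true_sq_distances(pat)
            acc = d if acc is None else acc + d
        mean_d = acc / 200
        iu = np.triu_indices(len(conditions), 1)
        sel_lex = lex.mask.intersect(across).indicator[iu]
        lex_pred = lex.predictions[iu][sel_lex]
        tau_lex = kendall_tau_a(mean_d[sel_lex], lex_pred)
        sel_sub = sub.mask.intersect(across).indicator[iu]
        tau_sub = kendall_tau_a(mean_d[sel_sub], sub.predictions[iu][sel_sub])
        # same-word across-type distances are exactly 0, all different-word
        # distances are positive, so tau-a hits the lexical tie ceiling
        a, b = np.triu_indices(lex_pred.size, 1)
        tau_max = (np.sign(lex_pred[a] - lex_pred[b]) != 0).mean()
        assert tau_lex == pytest.approx(tau_max, abs=1e-12)
        assert abs(tau_sub) < 0.1

    def test_roi_outside_mask_rejected(self, conditions):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[:4] = True
        geom = sf.VolumeGeometry(shape=(8, 8, 8), mask=mask)
        eff = sf.EffectSpec(roi_center=(6, 6, 6), roi_radius=1.0)
        with pytest.raises(ValueError):
            sf.plant_condition_patterns(geom, conditions, eff, 0)


class TestTimeseries:
    def test_zero_everything_constant(self, geom, conditions, hearing_spec):
        run = sd.generate_run_sequence(hearing_spec, 1, seed=0)
        pat = np.zeros((32, geom.n_voxels))
        noise = sf.NoiseSpec(temporal_sd=0.0, drift_sd=0.0)
        data, events, motion = sf.simulate_timeseries(
            pat, run, hearing_spec, geom, noise, 0
        )
        assert np.allclose(data, 0.0)
        assert motion.shape == (175, 6)

    def test_hrf_peak_near_six_seconds(self):
        t = np.arange(0, 32, 0.1)
        h = double_gamma_hrf(t, HRFParams())
        assert t[np.argmax(h)] == pytest.approx(6.0, abs=0.3)

    def test_single_event_response_peaks_post_onset(self, conditions, hearing_spec):
        """An isolated trial's response peaks at the volume nearest onset+6s."""
        geom = sf.VolumeGeometry(shape=(6, 6, 6))
        run = sd.generate_run_sequence(hearing_spec, 1, seed=1)
        first_stim = next(t for t in run.trials if t.kind == "stimulus")
        pat = np.zeros((32, geom.n_voxels))
        labels = [c.label for c in conditions]
        k = labels.index(first_stim.stimulus.condition.label)
        pat[k, :] = 1.0
        noise = sf.NoiseSpec(temporal_sd=0.0, drift_sd=0.0)
        data, *_ = sf.simulate_timeseries(pat, run, hearing_spec, geom, noise, 0)
        v = data[:, 0]
        onset = first_stim.onset + sd.STIMULUS_ONSET_DELAY
        tr = hearing_spec.trial_duration
        # restrict to the volumes before the next same-condition trial
        peak_vol = int(np.argmax(v[: first_stim.index + 4]))
        expected_vol = int(np.round((onset + 6.0) / tr))
        assert abs(peak_vol - expected_vol) <= 1

    def test_ar1_lag1_autocorrelation(self, rng):
        x = sf._ar1_noise(rng, 100_000, 1, sd=1.0, rho=0.3).ravel()
        xc = x - x.mean()
        r1 = (xc[1:] * xc[:-1]).sum() / (xc**2).sum()
        assert r1 == pytest.approx(0.3, abs=0.02)


class TestCohort:
    def test_determinism(self, geom, hearing_spec, effect):
        kw = dict(
            paradigm=hearing_spec, geometry=geom, effect=effect,
            noise=sf.NoiseSpec(), cohort=sf.CohortSpec(4), seed=5,
        )
        a = sf.generate_cohort(**kw)
        b = sf.generate_cohort(**kw)
        assert all(
            np.array_equal(x.betas.betas, y.betas.betas)
            and x.reading_score == y.reading_score
            for x, y in zip(a, b)
        )

    def test_subject_patterns_independent(self, geom, hearing_spec, effect):
        subs = sf.generate_cohort(
            hearing_spec, geom, effect, sf.NoiseSpec(beta_noise_sd=0.0),
            sf.CohortSpec(3), seed=9,
        )
        roi = geom.sphere_mask(effect.roi_center, effect.roi_radius)[geom.mask]
        a = subs[0].betas.betas[0][:, roi].ravel()
        b = subs[1].betas.betas[0][:, roi].ravel()
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.1

    def test_reading_effect_correlation_matches_bivariate_oracle(self, rng):
        """Cohort reading~effect correlation agrees with the direct bivariate
        simulation of the same truncated-normal + linear model (no fMRI)."""
        reading = sf.ReadingModel()
        base, spread = 1.0, 0.6
        # oracle: direct simulation of (g, reading) without the fMRI layer
        from scipy.stats import truncnorm

        a = (0 - base) / spread
        g = truncnorm.rvs(a, np.inf, loc=base, scale=spread,
                          size=200_000, random_state=rng)
        score = reading.intercept + reading.slope * g + rng.standard_normal(
            g.size
        ) * reading.residual_sd
        oracle_rho = np.corrcoef(g, score)[0, 1]
        assert oracle_rho == pytest.approx(0.5, abs=0.03)

        # cohort draws follow the same law
        geom = sf.VolumeGeometry(shape=(5, 5, 5))
        eff = sf.EffectSpec(roi_center=(2, 2, 2), roi_radius=1.0)
        gs, scores = [], []
        for seed in range(60):
            subs = sf.generate_cohort(
                sd.ParadigmSpec(), geom, eff, sf.NoiseSpec(),
                sf.CohortSpec(10, effect_base=base, effect_sd=spread), seed=seed,
            )
            gs.extend(s.effect_scale for s in subs)
            scores.extend(s.reading_score for s in subs)
        r = np.corrcoef(gs, scores)[0, 1]
        assert r == pytest.approx(oracle_rho, abs=0.06)

    def test_beta_null_case_breaks_reading_link(self, geom, hearing_spec, effect):
        """Zero reading slope: reading carries no effect-scale information."""
        reading = sf.ReadingModel(slope=0.0)
        gs, scores = [], []
        for seed in range(40):
            subs = sf.generate_cohort(
                hearing_spec, sf.VolumeGeometry(shape=(5, 5, 5)),
                sf.EffectSpec(roi_center=(2, 2, 2), roi_radius=1.0),
                sf.NoiseSpec(), sf.CohortSpec(10), seed=seed, reading=reading,
            )
            gs.extend(s.effect_scale for s in subs)
            scores.extend(s.reading_score for s in subs)
        assert abs(np.corrcoef(gs, scores)[0, 1]) < 0.12

    def test_timeseries_mode_shapes(self, hearing_spec):
        geom = sf.VolumeGeometry(shape=(5, 5, 5))
        eff = sf.EffectSpec(roi_center=(2, 2, 2), roi_radius=1.5)
        subs = sf.generate_cohort(
            hearing_spec, geom, eff, sf.NoiseSpec(), sf.CohortSpec(3),
            seed=3, mode="timeseries",
        )
        rec = subs[0]
        assert len(rec.timeseries) == 4
        assert rec.timeseries[0].shape == (175, geom.n_voxels)
        assert len(rec.events[0]) > 0
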