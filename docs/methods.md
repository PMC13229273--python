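# Methods

This note documents the models, parameter choices and numerical decisions in
`phonorsa`, what the synthetic generator does and does not emulate, and the
known limitations of each stage.

## Paradigm generator

A run is 170 trials of 3.95 s (one sparse-sampling volume each): 128
stimulus, 10 null, 16 target and 16 decision trials.  Stimulus trials are
two blocks of 64, each containing every unique stimulus once, shuffled with
a repair pass so no lexical word occupies two consecutive stimulus-bearing
trials (targets included; nulls and decisions break adjacency).  Decision
trials are placed immediately after their target.

The published design reports *observed* spacing summaries, not the original
sampler, so spacing is generated directly from those summaries: gaps between
successive null trials are drawn from round(Normal(17, 3)) rejection-sampled
into [8, 26]; target-to-target gaps from round(Normal(11, 2)) into [7, 14].
The first null is the run-start rest trial (index 0).  Sixteen targets with
mean gap 11 nearly fill a 170-trial run, so the feasibility rejection
(cumulative-sum bound) slightly compresses the realized mean; over 1,000
runs the mean null gap is ≈ 16.9 and the SD ≈ 2.9, matching the printed
mean 17 / SD 3.  All bounds are `ParadigmSpec` fields.

Session-level target balance (all 64 unique stimuli as target exactly once;
per run: all 8 words per type, forms 4+4, exemplars 4+4) is constructed from
stacked 4×4 Latin squares over the (form, exemplar) cells, so the balance
holds by construction rather than by rejection.

Stimulus durations are drawn once per unique stimulus, uniformly within the
published per-type ranges (visual speech 1.04–1.36 s, auditory 0.558–0.972 s,
dynamic text 1.00–1.32 s), and held fixed across repetitions.

## Theoretical RDMs

Model predictions are small integers (0–3 or 0/1); only ranks matter because
fits use Kendall tau-a.  "Same word" in the Sublexical exclusion means
lexical identity: pairs of one word in different forms *or different
stimulus types* are excluded, since the model's purpose is to remove every
identity-driven source of similarity.  Cross-type pairs are unordered; each
is stored once.

A consequence of tau-a worth stating: for a model with tied predictions,
tau-a cannot reach 1 even for data exactly proportional to the model — tied
pairs contribute zero to the numerator but remain in the n(n−1)/2
denominator.  Exactness tests therefore assert attainment of the
tie-adjusted ceiling (#untied pair-pairs / all pair-pairs), not 1.0.

## Synthetic fMRI

**Patterns.**  Within a spherical ROI, condition patterns are linear
combinations of independent standard-normal basis patterns: per-phoneme
(modality-shared), per-(type, phoneme) (modality-specific), per-word
(lexical) and per-form components.  Expected squared pattern distance
between words i and j from the shared component alone is
`2 w² (3 − shared(i,j)) · ROI size` — exactly proportional to the Shared
Phonemes model, which is what makes recovery testable.  Basis patterns are
drawn independently per subject (group inference is subject-level, not
pattern-level).

**Defaults (frozen by pilot).**  The published work gives no anchor for
plausible crossnobis magnitudes, so component weights and noise were set
once by pilot simulation targeting two constraints: across-stimulus group
t statistics near the 3–5 band at n = 22–25, and ≥ 90% two-step recovery at
n = 12.  The frozen point — `w_shared_phon = 0.30` (× subject effect scale),
`w_modality_phon = 0.35`, `w_lexical = 0.20`, `w_form = 0.15`,
`beta_noise_sd = 4.5`, between-subject effect SD 0.6 — yields t ≈ 5.0
(Sublexical across) and ≈ 6.1 (Shared Phonemes across) at n = 25; the
recovery constraint was given priority where the two conflicted.  These are
package defaults, not claims about the brain.

**Reading model.**  `reading = 30.08 + 3.692 · g + Normal(0, 3.464)` with
effect scale `g ~ TruncNormal(1, 0.6; g > 0)`.  The slope uses the
*truncated* SD of g (0.5417), giving planted correlation ρ = 0.5 and reading
mean 34 / SD 4 (raw test points, matching the hearing group's summary).

**Timeseries mode.**  175 volumes per run (170 trials + 5 tail).  Each
stimulus-bearing trial contributes its condition pattern scaled by a
double-gamma HRF (peak 6 s, undershoot 16 s, ratio 6; gamma shape =
delay/dispersion + 1 so the mode sits exactly at the stated delay) convolved
with the stimulus-duration boxcar on a 100 ms grid and sampled at volume
times.  Stimulus onsets sit 2.5 s into the trial (the silent gap after the
2.45 s readout).  Noise is AR(1) per voxel (marginal SD 1, ρ = 0.3),
spatially smoothed (4 mm FWHM); slow cosine drift and six random-walk motion
traces are added/returned.  Beta mode skips all of this: per-run betas =
true pattern + i.i.d. Gaussian noise, residuals white — appropriate for
replicate studies of the distance/searchlight/group stages, and the regime
in which diagonal noise normalization is exact.

**Not emulated:** BOLD nonlinearity, physiological noise, motion *in* the
data (motion regressors are pure nuisance), susceptibility dropout,
between-run misalignment, non-spherical ROIs.  A green recovery test
establishes that the pipeline recovers the geometry it was told to plant at
realistic SNR — not that real cortex behaves this way.

## First-level GLM

36 task regressors per run (32 conditions × 4 trials each, 2 target-by-type,
decision cue, button) plus optional motion and a session mean; nulls are the
implicit baseline.  Drift handling projects the sub-cutoff (350 s) DCT basis
out of design and data; with 175 × 3.95 s runs that basis has 3 components.
Autocorrelation: a single pooled lag-1 coefficient per run estimated from
OLS residuals, then one Cochrane–Orcutt-style prewhitened refit (first
sample scaled by √(1−ρ²)).  This is deliberately simpler than SPM's
hyperparameterized AR model but testable: planted ρ = 0.4 is recovered to
±0.03 and whitened residual autocorrelation is ≈ 0.

## Crossnobis

Distances are normalized by voxel count (per-voxel units) so values are
comparable across searchlight spheres of different sizes (mask edges).
Noise covariance: run-wise residual covariances averaged, then shrunk toward
their diagonal with the Ledoit–Wolf/Schäfer–Strimmer analytic intensity
(`shrinkage="auto"`), preserving voxel variances and guaranteeing positive
definiteness.  Whitening uses the symmetric inverse square root via
eigendecomposition.  The vectorized estimator uses
`Σ_{m≠n} d_m·d_n = ‖Σ_m d_m‖² − Σ_m ‖d_m‖²` and is tested to 1e-10 against
a literal fold-pair loop.

## Searchlight and cluster inference

Default sphere radius 3 voxels (9 mm at 3 mm isotropic; the source work does
not print its radius).  Two engines: per-sphere full-covariance whitening
(reference), and a fast engine with per-voxel (diagonal) normalization whose
per-voxel distance contributions are additive over spheres, reducing maps to
one sparse neighborhood aggregation.  With shrinkage fixed at 1 the sphere
engine collapses onto the diagonal engine exactly — asserted in tests.

Cluster-forming: one-tailed peak p < 0.001 on each stimulus type's
one-sample t map, conjunction = both types suprathreshold (minimum-t
statistic), 26-connected components.  Cluster p-values come from a sign-flip
permutation null of the maximum cluster size (min(2ⁿ, 10,000) flips;
subject maps are mean-centered implicitly by the sign flips under the
symmetric-null assumption), then BH-FDR across clusters at q < 0.05.
Below 8 subjects a warning notes the coarse permutation resolution.  The
one-tailed direction is fixed positive throughout: crossnobis distances and
model fits are predicted positive, negative values being estimation noise.

## Group statistics

tau-a (not tau-b) by explicit choice; Fisher z before group t-tests;
Bonferroni families equal the number of clusters tested at a given step,
not the number of models.  The two-step gating means downstream tests run
only where their gate passed — absent rows in the output are by design.
Segment-position contrasts use a one-way repeated-measures ANOVA
(F = MS_position / MS_subject×position), df = (2, 2(n−1)).  Brain–behavior
correlations are Pearson r with one-tailed p via t = r√(n−2)/√(1−r²); we
report n and df = n−2 explicitly.  Classical MDS uses Torgerson double
centering; negative crossnobis distances are clamped to zero with a warning
(unbiased estimates may be negative; classical MDS requires dissimilarities).

## Numerical and degenerate-input decisions

- Correlations at ±1 are clamped by 1e−7 before atanh, with a warning.
- Zero-variance inputs (t-tests, correlations, covariance voxels) raise
  errors naming the offending quantity rather than returning NaN.
- Constant model predictions make tau-a's direction undefined and raise.
- RM-ANOVA sums of squares below 1e−12 of the data's scale are treated as
  zero (F = 0 rather than a 0/0 float artifact).
- All randomness flows through explicit integer seeds; identical seeds give
  bit-identical cohorts, sequences and pipeline outputs.

## Limitations

The cluster-level permutation assumes sign-symmetric per-subject maps under
the null; crossnobis maps are symmetric around zero only without signal, so
cluster p-values are approximate near threshold.  The conjunction is the
minimum-statistic version (valid but conservative).  The pipeline accepts
externally estimated betas + residuals in place of its simulator, but raw
MRI preprocessing (realignment, normalization) is explicitly out of scope.
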