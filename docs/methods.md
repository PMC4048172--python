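# Methods

`paindecode` reimplements, as a tested pipeline on synthetic data, a
multivariate decoding analysis for chronic low-back pain: per-subject fMRI
contrast maps (painful electrical stimulation vs rest) restricted to a
pain-processing region mask are classified as *chronic* vs *normal* by a
sparse Bayesian logistic regression, evaluated with leave-one-out
cross-validation (LOOCV), and accompanied by permutation, posterior and FDR
inference plus univariate and demographic companion statistics.  The
original subject data are not public, so every stage runs on cohorts from
the package's own generator, and the generator's defaults encode the study
conditions: 13 subjects per group, a ~6686-voxel mask at 2 mm in MNI space,
TR 3.67 s, 86 scans per run, two runs, 14 s stimulation / 14 s rest
repeated five times.

## Synthetic cohorts (`paindecode.cohort`)

**Mask.** Five spheres on the 2 mm MNI grid labeled S1, S2, IPC, insula and
ACC (the regions of the original feature-selection mask), with radii chosen
once so the default mask holds 6839 voxels — within 5% of the 6686 of the
study.  Region labels are reporting metadata only; the decoder sees a flat
voxel vector.

**Contrast maps.** Each subject's map is `noise_sd × smoothed white noise`,
plus, for chronic subjects, a shift of `effect_size × noise_sd` at each
informative voxel.  The white-noise field is smoothed with a 3D Gaussian
kernel (default FWHM 8 mm, the smoothing kernel of typical preprocessing)
and divided by the analytic factor `(2√π σ)^(-3/2)` so the per-voxel SD is
exactly `noise_sd` again.  Effect sizes are therefore standardized
group-mean differences (Cohen's d).  The default ground truth places three
informative voxels at the canonical cluster peaks — two somatosensory
locations with d = −2 (chronic < normal) and one inferior-parietal location
with d = +2 — mirroring the sign structure of the reported clusters.

**What the generator does not emulate:** scanner artifacts, motion,
physiological noise, spatially extended (cluster-shaped) effects,
between-voxel noise heterogeneity, or site/scanner effects.  Passing tests
therefore demonstrate correctness of the statistical machinery under a
known, idealized data-generating process, not expected performance on real
fMRI.

**Demographics** are sampled to match the study table's marginals (ages
uniform 38–65, thresholds log-normal around 0.7 mA rounded to the protocol's
0.1 mA step, sex 9:4, handedness 10:2:1, ethnicity 10:3, chronic durations
0.5–5 y).  They feed only the companion statistics.  The study's actual
26-row demographics table ships as package data
(`load_reference_demographics`) for the reproducible desk-scale statistics.

**BOLD time series.** Optionally, per-voxel series `baseline +
responsiveness × (boxcar ⊛ HRF) + drift + AR(1) noise` are generated, with
the responsiveness maps drawn from the same contrast model.  Drift is a
random combination of the run's discrete-cosine components slower than the
high-pass cutoff — exactly the band the GLM removes — so the zero-noise GLM
round trip recovers the programmed responsiveness to 1e-8 (a free-frequency
drift sinusoid would leak into the task regressor and break exactness).
AR(1) noise is stationary with unit-lag coefficient `ar_coef` (default 0.3).

## First-level GLM (`paindecode.glm`)

Design: one task regressor (boxcar sampled at scan times, convolved with a
canonical double-gamma HRF — response peak 6 s, undershoot 16 s, ratio 6,
unit peak), per-run intercepts, and per-run non-constant DCT drift columns
with `K = floor(2·n·TR/cutoff) + 1` terms at cutoff 128 s (drift regressors
in the design are the projection equivalent of filtering the data).
Rank-deficient designs are rejected with the collinear columns named.

Serial correlation: two-pass AR(1) prewhitening.  The OLS residual lag-1
ratio is pooled over voxels within runs; because residuals are a projection
of the noise, that raw ratio underestimates the AR coefficient (drift and
intercept regressors absorb low-frequency noise power — about 0.21 observed
for a true 0.3 with this design).  The estimator therefore inverts the
analytic map `phi → E[residual lag-1 ratio]` implied by the design's hat
matrix (a 21-point grid plus interpolation, cached per design).  Data and
design are then whitened by the AR(1) square-root inverse within runs and
refit; the contrast is the task beta (+1 weight, rest being baseline).
The correction makes recovery of φ = 0.3 essentially unbiased at the cost
of mildly inflated variance relative to the naive ratio; the pipeline pools
across mask voxels, where that variance is negligible.

## Sparse logistic regression with ARD (`paindecode.slr`)

Binary logistic regression with a per-feature Gaussian prior of precision
`α_i`.  Fitting alternates: (a) MAP weights by damped Newton–Raphson on the
penalized log-likelihood; (b) Laplace posterior covariance `S = H^{-1}`;
(c) MacKay evidence updates `α_i ← γ_i/w_i²`, `γ_i = 1 − α_i S_ii`;
(d) permanent pruning of features with `α_i >` 1e8.  Convergence is a
relative weight change below `tol` (1e-6).  The bias has a fixed precision
of 1e-10 and is never pruned.  Features are z-scored with training-fold
statistics only; test subjects are transformed with the stored constants
(leakage-free).  Ties at p = 0.5 go to the normal class — arbitrary but
fixed.

Numerics: Newton directions use a direct Cholesky solve for small active
sets and the Woodbury identity in sample space while the active set exceeds
2n, keeping every step O(n²·m); a few damped Newton steps are taken per
evidence update (the classic IRLS-within-evidence scheme — near convergence
the gradient check terminates the inner loop immediately).
The kernel is a single plain-array function compiled with numba when
available (permutation testing refits the model hundreds of thousands of
times); the identical code runs un-compiled otherwise.  Defaults
(`alpha_init` 1, `prune_threshold` 1e8, `max_iter` 500, `tol` 1e-6) are
conventional ARD settings, exposed in the configuration.

Behavior worth knowing: this Laplace/MacKay realization retains ~5–8
features on paper-scale cohorts — sparser than the 6686 inputs by three
orders of magnitude, but not as aggressive as variational sparse logistic
regression, which reported ~3.  On linearly separable data (always, at
n ≪ p) retained weights grow until the evidence update balances them;
fits that exhaust `max_iter` are returned flagged rather than discarded.

## Evaluation and inference (`paindecode.evaluate`)

LOOCV holds each subject out once (26 independent fits).  The performance
report carries accuracy, sensitivity, specificity, PPV, NPV; d′ =
z(hit) − z(false alarm) with exact-0/1 rates pulled in by the 1/(2N) rule;
and the Beta-posterior accuracy under a uniform prior — mean
`(k+1)/(n+2)` and central 95% interval of `Beta(1+k, 1+n−k)`.  For the
study's 24/26 outcome this interval is [75.7%, 97.6%].

Accuracy significance: labels are shuffled across subjects (one shuffle per
rerun, group sizes preserved) and the full LOOCV repeated B times;
p = (1 + #{null ≥ observed}) / (B + 1), which cannot be zero and is valid
for any B.  Per-rerun seeds are spawned deterministically from one seed.

Selection-count significance: the observed statistic is the number of folds
retaining each voxel.  Two null constructions are provided.  With
cohort-level shuffles the 26 folds of a rerun share 24–25 subjects and the
decoder stably re-selects the same spurious voxels, so null counts saturate
near the fold count and the test has no power — a degeneracy of
deterministic sparse learners on near-identical folds.  The default null
(`selection_count_null(per_fold=True)`) therefore re-shuffles the training
labels independently for every fold, decorrelating selections across folds;
observed counts near the fold count then stand out, matching the regime in
which counts of 9–25 out of 26 were reported as significant against null
maxima below ~8.  Per-voxel p-values against the pooled (voxels ×
permutations) null are corrected by Benjamini–Hochberg at q = 0.05; a
max-statistic null is available as a flag.

## Companion statistics (`paindecode.groupstats`)

Pooled-variance two-sample t per voxel with BH-FDR flags (zero-variance
voxels masked with a warning); threshold-weighted maps (per-subject
multiplicative scaling before the group test — the plainest reading of
"weighted by pain threshold level"); per-voxel Pearson correlation with
symptom duration converted to t with n−2 dof (perfect correlations guarded
to the largest representable statistic); spherical small-volume correction
(FDR restricted to an 8 mm-radius sphere); Wilcoxon rank sum with full
enumeration of group assignments for combined n ≤ 12 and a tie- and
continuity-corrected normal approximation above; a Lilliefors-type
normality test (KS statistic against a normal with estimated parameters,
Monte-Carlo p, since table p-values assume known parameters); post-hoc
power for two proportions by the classical normal approximation (pooled
variance under the null, unpooled under the alternative, both rejection
directions summed — equal proportions give power ≈ α); and head-motion
summaries (summed scan-to-scan |difference| and total within-session
deviation per realignment parameter, compared by two-sample t per
parameter).  The power formula agrees with direct simulation of the z-test
to about 3 points at mid-range proportions (n = 50) — the intrinsic
accuracy of the approximation, not an implementation error.

## Problem sizes used by the test suite

All heavy checks are Monte-Carlo experiments whose sizes are fixed in the
tests: decoder recovery uses 50 full-scale cohorts (13+13, 6839 voxels,
d = 2); the null-accuracy check 100 full-scale cohorts; permutation
calibration 100 null cohorts at B = 99 on a small 8-voxel unsmoothed mask
(type-I calibration of a permutation test follows from label
exchangeability and does not depend on voxel count); module-level
Monte-Carlo checks use a few hundred voxels and tens of repetitions.
Seeds are fixed throughout; rerunning the suite reproduces every number.

## Known limitations and observed deviations

- At the study's conditions (three point-informative voxels at d = 2 among
  ~6686, n = 25 training subjects) LOOCV accuracy reaches 90% in only
  about a third of simulated cohorts — and independent sparse baselines
  (L1 logistic regression) do no better, while dense classifiers sit at
  chance.  An oracle using the true three voxels would exceed 95%; the gap
  is the cost of feature selection at n = 25.  High decoding accuracy on
  real data of this shape implies effects that are stronger, spatially
  extended, or both.
- Null-cohort LOOCV accuracy averages ~46%, below the nominal 50%: with
  balanced groups every training fold is imbalanced 12-vs-13 against the
  held-out subject's class, the familiar pessimistic bias of leave-one-out
  with discriminative classifiers.  The permutation test is built on the
  same statistic and therefore remains exactly calibrated (measured
  rejection rate 3% at α = 0.05).
- d′ for 12/13 sensitivity and specificity is 2 Φ⁻¹(12/13) ≈ 2.852 under
  the standard convention implemented here.
- The generator's point effects make selection-count inference conservative
  compared to spatially extended real effects.
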