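# Methods

## The analysis in one paragraph

A prediction pipeline is trained per feature block: winsorize at the
training mean ± 3 SD, center and scale to unit variance (population SD),
reduce by PCA to *n*−1 components when features outnumber training
subjects, and fit an ℓ2 linear model (ridge regression for the continuous
strength score, ℓ2 logistic regression for sex) whose inverse penalty C is
chosen by nested 5-fold cross-validation — first over the decade grid
C = 10⁻⁵ … 10⁵, then over 11 log-spaced points spanning one decade either
side of the coarse optimum, ties breaking toward the strongest penalty.
Blocks are combined by pre-validated stacking: within a seeded 10-fold
split of the training set, each first-level pipeline (including its
processing and C selection) is refit per fold and its out-of-fold
predictions become the regressors of an unregularized second-level model;
at test time the first-level models are refit on the full training set.
Confound correction is itself train-fitted: sex correction demeans every
feature and the target by the training means of each sex; strength
correction replaces each feature by the residual of a per-feature linear
fit on the strength score. Held-out performance uses MAE, RMSE and the
holdout R² (against the test-set mean of the measured scores; negative
when the model underperforms that constant baseline), or accuracy at the
0.5 threshold and the rank-statistic AUC. Significance of held-out
performance comes from permuting the raw training target and refitting
the entire pipeline per draw; coefficient reliability comes from
bootstrap resampling of training rows with the penalty frozen at the
full-train selection, Z = bootstrap mean/SD per original feature
(inverse-PCA back-projection where PCA was used), two-tailed normal p,
and Benjamini–Hochberg control at q < 0.05.

## Tangent connectivity

Subject covariances are estimated per run from band-passed
(0.008–0.100 Hz, order-5 Butterworth applied forward–backward, default
sampling interval 0.72 s) region timeseries with Ledoit–Wolf shrinkage,
which stays positive definite when timepoints are comparable to regions.
The group reference is the affine-invariant geometric (Karcher) mean of
the training covariances: a fixed-point iteration started at the
arithmetic mean, converged when the Frobenius norm of the tangent-space
mean falls below 10⁻⁶ (50 iterations maximum; the arithmetic mean is
available as a configuration option since either choice is defensible).
Each covariance C maps to log(G^{-1/2} C G^{-1/2}); the strict lower
triangle, vectorized row-major without √2 off-diagonal scaling, gives
r(r−1)/2 features — 7,381 for 122 regions — and per-subject features are
the elementwise mean over runs. The reference is fitted on training
subjects only and never updated at projection time.

## The synthetic cohort generator

The generator defines the study conditions; it is not a tuning dial. Per
subject, sex is Bernoulli (54% female) and a standard-normal latent z
("neural strength factor") is drawn; the strength score is
mu(sex) + sd(sex)·(ρ_z·z + √(1−ρ_z²)·ε) with the study cohort's training
values mu = 109.1/125.5 and sd = 6.0/9.1 (female/male; sample Cohen's
d ≈ 2.1). Each tabular block is rank-2 signal plus unit Gaussian noise:
w_sex·s·uᵀ + w_strength·z·vᵀ, with s = −1/+1 the sex code and u, v fixed
unit loading vectors per block. Region timeseries are drawn from
per-subject covariances Σ_base + a_sex·s·M_sex + a_strength·z·M_str
(AR(1)-like base, symmetric unit-norm perturbations, eigenvalues floored
at 10⁻³ of the mean eigenvalue after shrinking the perturbation if
needed), two runs per subject. Age (uniform 22–37), handedness (91%
right) and family membership are nuisance columns with no feature signal;
the family-size distribution is configuration, and the test split draws
at most one subject per family so familial structure never spans the
train/test boundary.

Default loadings: w_sex = 2.0, w_strength = 1.0, noise SD 1, ρ_z = 0.3.
The calibration logic: a linear model can recover a binary latent with
squared correlation at most w²/(1+w²), so w_sex = 2.0 caps the
sex-mediated share of strength variance at 0.8 of its 0.54 variance
fraction, giving held-out uncorrected R² around 0.35–0.45 at n = 600 —
the range a strong single modality reaches in practice — while
w_strength = 1.0 with ρ_z = 0.3 leaves a small residual signal so the
sex-corrected R² sits near zero. Sex classification from the same blocks
runs at ≈ 95% accuracy, dropping markedly after strength
residualization. What the generator deliberately does not emulate:
spatial autocorrelation of real features, site/scanner effects,
heavy-tailed measurement noise, non-linear sex–feature relationships, and
genuine genetic relatedness (families are labels only). Tests passing on
these cohorts therefore validate the machinery and the logical structure
of the confound argument, not any claim about real neuroimaging data.

## Numerical and design choices

- SD convention: population (divide by n) for winsor bounds and scaling;
  immaterial at study sizes, fixed for determinism.
- PCA sign convention: each component's largest-absolute loading is made
  positive, so back-projected coefficient maps are reproducible.
- Back-projected coefficients live on the standardized features (PCA is
  inverted; scaling is not), matching how coefficient maps are usually
  read.
- Correction order: confound correction precedes winsorize/scale/PCA; the
  internal processing order is winsorize → scale → PCA.
- Classification C selection scores with log-loss (a proper scoring rule;
  the regression pipelines use MSE as stated). Classification folds are
  stratified; regression folds are not. All fold assignments are seeded.
- Permutation p-values use additive smoothing (1+k)/(1+B), so p is never
  zero and is valid under exchangeability. For the stacked model the
  permutation refits the whole stack end to end.
- For sex-corrected regression both features and target are demeaned and
  metrics are computed against the demeaned test scores (training sex
  means); for strength-corrected classification only features are
  residualized. In the corrected multimodal model the second-level target
  correction is fit on the full training set while per-fold first-level
  fits carry their own corrections.
- Degenerate inputs: constant features pass through winsorization
  unchanged and are centered-only in scaling (logged); zero-SD bootstrap
  coefficients get p = 1 and a flag; rank-deficient stacking falls back
  to the minimum-norm solution (logged); a test-time group unseen in
  training raises.

## Problem sizes

Simulations run at desk scale, chosen as the smallest sizes at which the
phenomena are stable: the confound-collapse study uses 20 seeded cohorts
of 600 training / 75 unrelated test subjects on the 155-feature
morphometry block; permutation calibration uses 200 replicates at B = 99
with n = 40/20 and 5 features; bootstrap recovery uses n = 500, 50
features, B = 200. Permutation and bootstrap defaults are B = 1,000,
configurable up to 10,000 for full-scale runs.

## Coefficient-recovery design

Bootstrap-Z inference tests multivariate model coefficients, so a planted
feature is only recoverable if it is *conditionally* informative. With
rank-one loading vectors spread over many features, redundant features
measuring one latent saturate: past a handful of markers, each additional
feature adds almost no unique information and its conditional t-statistic
stays small no matter how large the loading — a partial-correlation
calculation and an OLS t-value simulation both confirm this. The recovery
study therefore plants small supports (two features per loading vector,
equal magnitudes, via the generator's `equal_loadings` option) with
w_sex = 2.0, w_strength = 1.4, ρ_z = 0.8, where the expected conditional
t of every planted feature is ≈ 6–9; sensitivity and false-positive rate
are measured against the known support.

## Known limitations

- The timeseries block's covariance perturbations are dense random
  matrices, not network-structured, so connectivity coefficient maps have
  no anatomical interpretation.
- The permutation test assumes exchangeability of training subjects; the
  family structure is ignored when permuting (as is standard), which is
  exact only because the generator plants no family effects.
- Bootstrap Z→p uses the normal approximation and ignores bootstrap
  distribution asymmetry.
- The handedness χ² from the source cohort description is not
  reproducible from printed counts alone (the category structure is
  ambiguous) and is not asserted anywhere.
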