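# neuroconfound

Confound-aware multimodal brain-feature prediction: an end-to-end analysis
of what happens to predictive models when a binary attribute (sex) is
entangled with the outcome they predict (grip strength).

## The problem

Brain-based predictive models are attractive as biomarkers: given a table
of gray-matter morphometry, white-matter fractional anisotropy, resting
state functional connectivity, or task-activation features, an ℓ2 linear
model can predict a continuous phenotype such as grip strength with
substantial held-out R². But grip strength is strongly bimodal by sex
(Cohen's *d* > 2), so a strength model may in fact be decoding sex — a
confound that makes the model useless as a biomarker of neuromuscular
function even when its accuracy looks excellent. This package implements
the full machinery needed to expose and quantify that ambiguity:

- **synthetic cohorts** with a planted sex confound, a sex-independent
  "neural strength" latent, multimodal feature blocks, family structure,
  and region timeseries (`neuroconfound.synthetic`);
- **tangent-space functional connectivity** with a training-only reference
  (band-pass 0.008–0.100 Hz, Ledoit–Wolf covariances, affine-invariant
  geometric mean, matrix-log embedding; 122 regions → 7,381 features)
  (`neuroconfound.connectivity`);
- **train-fitted processing**: winsorization at mean ± 3 SD, unit-variance
  scaling, PCA to *n*−1 components when features outnumber subjects
  (`neuroconfound.preprocessing`);
- **ℓ2 regression and classification** with two-stage nested 5-fold CV over
  the decade grid C = 10⁻⁵ … 10⁵ (`neuroconfound.models`);
- **pre-validated multimodal stacking**: 10-fold out-of-fold first-level
  predictions feeding an unregularized second-level model
  (`neuroconfound.stacking`);
- **train-safe confound correction**: group demeaning of features and
  target, and per-feature residualization on a continuous covariate
  (`neuroconfound.confounds`);
- **held-out evaluation** (MAE, RMSE, holdout R² = 1 − Σ(yᵢ−pᵢ)²/Σ(yᵢ−ȳ)²,
  accuracy, AUC) with permutation significance that refits the entire
  pipeline per shuffle (`neuroconfound.evaluation`);
- **bootstrap coefficient inference**: Z = bootstrap mean / SD per original
  feature (inverse-PCA back-projection), two-tailed normal p, BH FDR at
  q < 0.05, and Spearman comparison of coefficient vectors
  (`neuroconfound.inference`);
- **cohort statistics**: Cohen's *d*, summary t-test, 2×2 χ², Mann–Whitney
  U (`neuroconfound.cohort_stats`).

The `analysis/` directory holds the numbered study drivers; each is a thin
script over the library that prints what it found and writes delimited
tables under `results/`.

## Worked example

```bash
python analysis/03_strength_prediction.py
```

```
 seed  r2_uncorrected  r2_sex_corrected
    0           0.367            -0.024
    1           0.324            -0.104
    2           0.398            -0.002
    3           0.258             0.023
    4           0.436            -0.022

mean held-out R^2: uncorrected 0.357, sex-corrected -0.026
```

Each row is one seeded synthetic cohort (600 training subjects, 75
unrelated test subjects, the study's strength distribution). Without
correction the gray-matter pipeline appears to predict strength (held-out
R² ≈ 0.36); after demeaning features and target by sex (training means
only), R² collapses to ≈ 0 — the apparent signal was the confound. The
flipped analysis (`analysis/04_sex_classification.py`) shows the mirror
image: sex is classified from the same features with ≈ 96% accuracy, which
drops to ≈ 73% once the features are residualized on strength. Running
`analysis/06_coefficient_inference.py` shows why: the Spearman correlation
between the strength-model and sex-model coefficient vectors is ≈ 0.8 —
the two models use largely the same features.

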