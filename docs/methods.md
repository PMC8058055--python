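# Methods

## Overview

`normdev` implements a normative-modeling analysis of regional brain
features in a developing cohort. The pipeline has four stages:

1. **Normative models.** For each cortical region j, a Gaussian-process
   regression (GPR) of the feature (cortical volume) on age and sex is fit
   to a healthy training subset. The GPR supplies a predicted value
   ŷ_ij for subject i, a predictive uncertainty σ_ij at that subject's
   covariates, and a normative variance σ²_nj learned from the training
   residual structure. Every scored subject receives a deviation z-score

       z_ij = (y_ij − ŷ_ij) / √(σ²_ij + σ²_nj),

   negative z meaning lower-than-normatively-expected volume. Training
   subjects themselves are scored by k-fold cross-validation (each fold
   scored by models refit without it), so healthy controls can enter
   downstream case-control analyses without self-scoring bias.
2. **Prediction.** Repeated k-fold cross-validated ridge regression
   (penalty α = 1) predicts each of six orthogonal psychopathology
   dimensions from multivariate regional patterns — once from deviation
   z-scores, once from raw volumes. Within every training fold, age and
   sex are regressed out of the target and a PCA retains components
   explaining ≥ 1% variance; both transforms are fit on the training fold
   only. Error metrics are sign-flipped (negative RMSE/MAE) so higher is
   always better. Significance comes from a permutation null over shuffled
   targets (one-sided proportion of permuted scores ≥ the observed mean,
   no smoothing), BH-FDR corrected across dimensions; feature kinds are
   compared with a paired sign-flip exact test over repeat-level scores.
3. **Regional associations.** Deviations averaged over named ROIs (unions
   of parcels) are correlated with each dimension after residualizing both
   sides on image-quality covariates (T1 QA, T1 SNR). For each ROI and
   each specific dimension, 10,000 bootstrap resamples of
   |r_overall| − |r_specific| give a percentile CI; the general factor is
   declared reliably stronger when the lower 99% bound exceeds zero. A
   whole-brain mass-univariate map correlates every parcel with every
   dimension in one BH-FDR family (e.g. 400 × 6 = 2400 tests).
4. **Case-control.** For each disorder group (depression, ADHD; comorbid
   subjects excluded from both), healthy controls are greedily 1:1 matched
   on age, sex, T1 QA and T1 SNR (exact sex match, standardized Euclidean
   distance on the rest, without replacement; the two disorders never
   share a control). Group abnormality is the map of regional Cohen's d
   (pooled-sd, (n−1)-weighted). The spatial Pearson correlation between
   the two disorders' d maps measures overlap; re-estimating after
   OLS-residualizing deviations on the general factor (separately within
   each case+control scope) shows how much overlap the general factor
   carries. A paired t test on |d_before| − |d_after| (positive t =
   shrinkage toward zero) tests the distribution shift.

## Gaussian-process specification

The framework fixes the regression family (GPR) but not a kernel. The
kernel here is

    k = C₁·RBF(standardized age) + C₂·DotProduct(age, sex) + White(σ²_n)

— a smooth nonlinear age trend, a linear trend over both covariates with
an additive sex offset, and a white-noise term whose fitted level is the
normative variance. σ_ij is the posterior predictive standard deviation
with the noise term removed, so the two variance terms in the z formula
remain distinct. Features are standardized per region on training
statistics; z-scores are invariant to this by construction (asserted in
tests at the optimizer's numerical reproducibility, ~1e-6). Hyperparameters
maximize the log marginal likelihood with configurable random restarts
(default 5); identical feature columns yield bit-identical models because
restart draws share one seed. Fitting is joint over (age, sex) rather than
sex-stratified — one model per region keeps the training subset intact for
both sexes and lets the data decide the size of the sex effect.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the study's scale (defaults: 1271 subjects aged 8–22, 47% male, 400
regions, 281-healthy training split):

- **Trajectories.** Regional volume follows a logistic-plus-linear decline
  in age with an additive sex offset; per-region curve parameters are
  drawn once from configurable priors (baseline ≈ 3000 mm³, logistic drop
  ≈ 350 mm³ around age 14, linear slope ≈ 12 mm³/yr, male offset
  ≈ 150 mm³ — magnitudes chosen to give volumes a robust global decline
  from childhood to adulthood with region-specific variation).
- **Factor scores.** Six dimensions (general + five specific) are
  Gaussian draws made exactly orthogonal by QR after centering, then
  scaled to unit variance. Raw scores are already Gaussian, so the
  rank-based inverse normal transformation (Blom offset
  (rank − 3/8)/(n + 1/4), average ranks for ties) acts as a near-identity
  check; it exists for ingesting skewed real factor scores.
- **Deviations.** Each region's latent deviation is
  Σ_k r_k·F_k + √(1 − Σ r²_k)·ε, so a configured effect (region set,
  factor, r) is the exact population correlation between factor and
  deviation. Volume = trajectory + region_sd · deviation. The default
  effect map places negative general-factor effects (r −0.15 … −0.11) in
  four a-priori ROIs (vmPFC/mOFC, inferior temporal, daCC, insula),
  weaker fear and psychosis-positive effects in subsets, and
  disorder-specific anxious-misery / externalizing effects in disjoint
  region blocks — so case-control d maps share a general-factor pattern
  plus disorder-specific patterns.
- **Groups.** Depression requires anxious-misery > 0.75 and general
  factor > 0.25; ADHD analogously via externalizing; comorbid subjects
  become other-clinical (the two case groups are mutually exclusive);
  healthy requires all six scores < 0.9. At n = 1271 this yields roughly
  380 healthy, 100–130 per case group, mirroring the study's composition.
- **Optional heteroscedasticity.** Residual sd may grow linearly with age
  to exercise the GPR's variance estimation; default homoscedastic.

What the generator does **not** emulate: item-level symptom responses and
the confirmatory bifactor fit (factor scores are emitted directly);
scanner/site effects; spatial autocorrelation between neighboring parcels
(regions are independent given the factors); non-Gaussian residuals.
Passing tests therefore show the machinery is correct and calibrated under
the generative assumptions, not that real cortical data satisfy them.

## Numerical and design choices

- **Permutation nulls.** The target is permuted once per permutation and
  the CV pipeline rerun at one fold layout per permutation (configurable).
  Per-fold PCA bases, nuisance projectors, and the ridge solve matrix
  depend only on features, covariates, and fold assignment, so they are
  computed once per layout and reused across permutations — numerically
  identical to naive reruns, orders of magnitude faster. Because observed
  scores average more layouts than each null draw, null p-values are
  mildly conservative; with one observed repeat they are exactly uniform.
- **Exact test.** Sign-flip enumeration uses half-split subset sums
  (all 2^n patterns for n ≤ 20); Monte-Carlo mode uses add-one smoothing
  so the smallest attainable p is 1/(n_mc + 1).
- **PCA component count.** When comparing feature kinds, the count
  selected on deviations is imposed on raw features (`n_override`) so both
  models see the same input dimensionality.
- **Bootstrap CI.** Percentile method; residualization is recomputed
  within every resample so the CI reflects covariate-adjustment
  uncertainty. Draws with a constant ROI column are redrawn and counted.
  Delta-r distributions are exactly antisymmetric under swapping the two
  dimensions (same seed, same resamples).
- **Matching ties and determinism.** Cases are visited in a seed-shuffled
  order; each takes its nearest unused control, so results are
  reproducible given the seed. Balance is reported as standardized mean
  differences; the pool must be strictly larger than the case group.
- **Degenerate inputs.** Constant feature columns get unit scale instead
  of 0; constant residual vectors, zero pooled sds, constant factors
  within a residualization scope, rank-deficient nuisance designs (the
  collinear columns are named), and region mismatches all raise.
- **Shift-test convention.** The d-distribution shift statistic is a
  paired t on |d_before| − |d_after|. A signed convention is ill-defined
  when a map mixes signs; absolute values implement "shift toward zero"
  directly.

## Problem sizes

Default test-suite and acceptance-script scales are chosen to exercise the
study's sample sizes where they matter statistically (281 training
subjects, ~990 test subjects, 100 healthy in test) while keeping region
counts (40–100), permutations (200), repeats (20), and bootstrap draws
(1,000–2,000) at desk scale; the `full` preset restores the full settings
(100 repeats, 10,000 bootstraps, up to 100,000 permutations).

## Known limitations

- The GPR treats regions independently; no spatial regularization or
  cross-region covariance.
- Normative models assume the healthy training subset is exchangeable
  with test-time healthy subjects (single site, one scanner); no transfer
  or harmonization across sites.
- The permutation null with >1 observed repeats is conservative (see
  above); the full-scale configuration (100 repeats vs single-layout
  nulls) inherits this.
- Greedy matching is order-dependent and not globally optimal; for
  heavily imbalanced covariates an optimal-matching method would balance
  better.
- Percentile bootstrap CIs undercover slightly in small samples; BCa is
  not currently wired in.
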