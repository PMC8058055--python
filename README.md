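# normdev

Normative neurodevelopmental modeling of regional brain features, with
transdiagnostic psychopathology-dimension analysis.

## The problem

Cortical gray matter changes markedly through childhood and adolescence,
and most mental disorders first surface in that window. Case-control
neuroimaging averages over clinically heterogeneous groups and keeps
finding the *same* regions across putatively distinct disorders — which
suggests those findings track a general liability to psychopathology (the
*p*-factor) rather than disorder-specific biology. `normdev` implements
the analysis framework that separates the two:

1. **Normative models.** Per region j, a Gaussian-process regression of
   cortical volume on age and sex, fit on healthy subjects only, yields a
   predicted volume ŷ_ij, predictive uncertainty σ_ij, and normative
   variance σ_nj. Every subject is scored as a deviation z-score

       z_ij = (y_ij − ŷ_ij) / √(σ²_ij + σ²_nj)

   — how far below (negative) or above their normatively expected volume
   they sit. Training subjects are scored leak-free by k-fold
   cross-validation.
2. **Prediction.** Repeated k-fold ridge regression (α = 1, within-fold
   PCA to components explaining ≥ 1% variance, leakage-safe age/sex
   nuisance regression on the target) predicts six orthogonal
   psychopathology dimensions (overall psychopathology + five specific
   factors) from deviations versus raw volumes, with permutation-null
   significance, BH-FDR correction, and a paired sign-flip exact test
   between feature kinds.
3. **Regional effects.** ROI-averaged deviations are correlated with each
   dimension (residualized for T1 QA/SNR); a bootstrap of
   |r_overall| − |r_specific| with 99% percentile CIs tests whether the
   general factor carries the larger effect; a mass-univariate map
   corrects all parcels × dimensions in one FDR family.
4. **Case-control.** Matched (age/sex/QA/SNR) Cohen's d deviation maps for
   depression and ADHD, their spatial correlation, and its attenuation
   after controlling deviations for overall psychopathology.

Because the motivating cohort is access-restricted, the package ships a
synthetic cohort generator that reproduces the statistical structure the
analysis assumes (nonlinear sex-dependent age trajectories, orthogonal
factor scores, factor-linked deviation effects in chosen region sets,
threshold-defined diagnostic groups). Every stage is tested against that
generator's ground truth. See `docs/methods.md` for the full model
description and design choices.

## Worked example

```python
import normdev as nd
from normdev.prediction import PredictionConfig, repeated_cv_predict

# synthetic study cohort: 1271 subjects, 80 regions, default effect map
cfg = nd.GeneratorConfig(n_subjects=1271, n_regions=80, seed=1)
cohort, volumes = nd.generate_cohort(cfg)

# healthy-only training subset; everyone else (plus 100 healthy) is test
split = nd.split_cohort(cohort, n_healthy_to_test=100, seed=1)
train = cohort[cohort.subject_id.isin(split.train_ids)]
test = cohort[cohort.subject_id.isin(split.test_ids)].reset_index(drop=True)

model = nd.fit_normative(volumes.loc[train.subject_id],
                         train.drop(columns="group"), n_restarts=1)
z = model.transform(test, volumes.loc[test.subject_id])   # deviation matrix Z

scores = repeated_cv_predict(
    z, test["p"].to_numpy(), test,
    PredictionConfig(n_repeats=20, seed=1),
)
print(f"corr(true, predicted p) = {scores['corr_true_pred'].point_estimate:.3f}")
```

On this cohort the held-out healthy subjects' z-scores are calibrated
(mean |per-region z mean| 0.09, mean per-region sd 1.02 — a correctly
specified normative model scores unseen healthy brains as roughly standard
normal), and the script prints

    corr(true, predicted p) = 0.565

Multivariate deviation patterns predict overall psychopathology out of
sample at r = 0.565, versus 0.485 from raw volumes of the same subjects
(same fold structure, same number of principal components) — the
deviation advantage the framework exists to demonstrate; the paired
sign-flip exact test over the 20 shared-fold repeats puts the difference
at p ≈ 2e-6.

The same pipeline is scriptable end to end:

```bash
normdev run --preset desk --out demo_run --seed 1
```

which writes the cohort, deviation matrices (test and cross-validated
training), prediction score tables, ROI bootstrap results, mass-univariate
map, case-control summaries, and a manifest with per-stage input/output
hashes (stages re-run only when their inputs change).

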