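# pclasso

Data-driven, voxel-based analysis of ROI-restricted parametric brain PET
images: **voxel-wise PCA** pattern discovery plus **LASSO-regularized
prediction** of clinical metrics (PC-LASSO), with back-transformation of
fitted models into interpretable voxel-weight estimator maps.

## Who this is for

Standard PET quantification averages tracer binding over a region of
interest and throws away the *spatial pattern* of binding inside it.  In
progressive disorders such as Parkinson's disease, that pattern carries
information about disease topology and stage.  `pclasso` is for imaging
researchers who have parametric binding-ratio (BR) images already resampled
into a common labeled template space (e.g. striatal images warped to a
shared grid) and per-subject clinical measures, and who want interpretable,
cross-validated, image-based predictive models rather than black-box
radiomic features.

## The method

1. **Binding ratio.** A parametric image is formed by dividing voxel
   activity by the mean activity in a nonspecific reference region:
   `BR = activity / mean(reference)`.
2. **Voxel-wise PCA.** Within one ROI and hemisphere, each template voxel is
   a variable and each subject an observation.  The centered data decompose
   as `f_n = mean + Σ_k s_nk ω_k`, where ω_k are orthonormal voxel-weight
   loadings (covariance patterns) ranked by variance accounted for (VAF),
   and s_nk are subject scores.
3. **PC-LASSO.** A clinical metric y is predicted from the top-J PC scores
   (and optional covariates) with L1-penalized least squares,
   `argmin_β ½ Σ_n (y_n − β_0 − Σ_j x_nj β_j)² + λ Σ_j |β_j|`,
   selecting λ over a linear grid from 0 to λ_max by repeated random
   holdout (default 500 splits at 70/30), reporting MSE_test (mean ± SE over
   splits), MSE_all at λ_min, and coefficient stability, against constant
   and mean-BR reference models on the *same* splits.
4. **Estimator maps.** Because PCA and LASSO are both linear, the fitted
   model is rewritten over voxels: `y = β_0 + (f · v)` with
   `v = Σ_j β_j ω_j`.  The map v assigns every voxel a signed weight whose
   sign is fixed by the fit, and is displayed as separate positive/negative
   maximum-intensity projections.
5. **Clinical quantities.** Adjusted disease duration
   `aDD = exp(−0.17·DD)`, renormalized to increase over the DD range; the
   lateral motor score (sum of seven lateralized limb items, tremor
   excluded); better/worse side assignment contralateral to the
   less/more-affected body side.

A **synthetic striatal phantom** (labeled ellipsoidal template, orthonormal
planted patterns, score/clinical couplings, hemispheric asymmetry, voxel
noise) makes the entire pipeline testable without external data.

## Worked example

`examples/03_predict_clinical.py` generates a 40-subject phantom whose
lateralized motor score is built from planted patterns 1 and 3, then compares
the three model families on shared splits:

```
constant model:  MSE_test   3.91 +- 0.15, MSE_all   4.00
mean-BR model:   MSE_test   1.14 +- 0.05, MSE_all   1.11
PC-LASSO model:  MSE_test   0.18 +- 0.01, MSE_all   0.12
lambda_min = 0.677 (grid 0..67.69 in 100 steps)
retained terms: PC1, PC2, PC3, PC5
```

The constant model's MSE is the outcome variance (no information); the
mean-BR model captures only the global binding level; PC-LASSO additionally
exploits the gradient pattern and cuts the test error by a further factor of
~6.  `examples/04_estimator_maps.py` back-projects that model into a voxel
map and verifies the score-space/voxel-space prediction identity
(`max |difference| 7.1e-15`) and its match to the generative truth
(`|cosine| 0.930`).  The other examples cover phantom generation, PCA
pattern recovery, and binding-ratio computation.

There is also a thin CLI:

```bash
pclasso phantom --output-dir out --n-subjects 40 --seed 0   # fixture + full demo
pclasso patterns config.json                                 # PCA panels
pclasso predict config.json                                  # model comparison
pclasso br activity.nii.gz reference_mask.nii.gz br.nii.gz   # binding ratio
```

## Scope

Images must already be in template space: acquisition, reconstruction,
smoothing, registration/warping and kinetic modeling are out of scope.  See
`docs/methods.md` for the model details, parameter defaults, numerical
choices and known limitations.
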