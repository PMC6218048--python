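# Methods

## Model and assumptions

`pclasso` operates on parametric binding-ratio (BR) images that are already
resampled into a common labeled template space, one image per subject per
hemisphere.  Three linear building blocks are composed:

**Covariance PCA over voxels.**  For one ROI and one hemisphere the data form
an N-subjects × V-voxels matrix.  After per-voxel mean removal the singular
value decomposition gives orthonormal voxel-weight loadings ω_k (rows of a
K × V matrix, K = min(N−1, V)), subject scores s_nk, and VAF_k = 100·σ_k²/Σσ²
(percent of total centered variance).  Voxels are *not* variance-scaled:
BR values are commensurate across voxels, and the leading component of
striatal BR data is a weighted mean of voxels, which per-voxel scaling would
destroy.  Because PCA leaves loading signs free, each loading is flipped so
its weight sum is nonnegative (scores flipped with it); a zero-sum balanced
gradient is resolved by making its largest-magnitude weight positive.

**L1-penalized regression of clinical metrics on scores.**  The objective is
½·RSS + λ·‖β‖₁ with an unpenalized intercept, solved by cyclic coordinate
descent with soft thresholding (convergence when the largest coefficient
change in a sweep is below 1e−8).  Predictors — PC scores and any clinical
covariates — are z-scored and penalized equally; the penalty is
scale-sensitive and nothing distinguishes the two kinds of input a priori.
Model selection uses repeated random holdout: the penalty grid is *linear*
from 0 to λ_max = max_j |x_jᵀ(y − ȳ)| in 100 steps (101 values); for each
grid value the data are split (default 500 times, test fraction 0.3, test
size round(0.3·N), sampled without replacement, one child seed per split
spawned from a master seed); standardization is recomputed on each training
split; λ_min minimizes the mean test MSE with ties broken toward the larger
(sparser) penalty; MSE_all is the full-data error of the full-data fit at
λ_min.  λ_max is computed once on the full standardized data and the same
grid is reused across splits.  Reference models — intercept-only and
one-predictor mean-BR least squares — are evaluated on the *identical* split
sequence.

**Voxel-space estimators.**  A fitted score model y = β₀ + Σ β_j s_j is
rewritten over voxels as y = β₀′ + (f − mean)·v with v = Σ β_j ω_j.
Coefficients are first mapped from the standardized-score scale back to the
raw-score scale (β_j/sd_j, with the means folded into the intercept), so the
score-space and voxel-space predictions agree to machine precision for every
subject.  The per-voxel mean enters through the centered form; equivalently
the constant mean·v could be folded into the intercept — the centered
convention is used so that "image equal to the mean image" predicts exactly
the intercept (plus covariate terms).  Covariate coefficients have no voxel
support and are reported beside the map, never folded into v.  Maps are
rendered as maximum-intensity projections with positive weights and
magnitudes of negative weights projected separately, both normalized by the
global maximum absolute weight.

**Clinical quantities.**  Adjusted disease duration linearizes the roughly
exponential decay of presynaptic binding with disease duration:
aDD = exp(rate·DD) (rate default −0.17/year, obtainable from an exponential
fit of mean BR against DD via `fit_add_rate`) followed by the affine
increasing renormalization fixed by the endpoints aDD(0) = 0 and
aDD(16) = 16 (defaults; the observed DD range).  The affine map is the
minimal choice consistent with "increasing with progression, spanning the DD
range".  The lateral motor score is the integer sum of seven lateralized
limb items (leg rigidity, toe tapping, leg agility, arm rigidity, finger
tapping, hand movements, pronation/supination), each 0–4; tremor items are
excluded because tremor correlates poorly with dopaminergic deficit.  The
worse *body* side has the larger lateralized total (ties default to the
right body side, with a warning — the choice only needs to be deterministic
and visible); the worse *brain* hemisphere is contralateral to it.  Which
items enter the side-assignment totals is configurable (default: all seven
lateralized items per side present in the table).

## The phantom: what it emulates and what it does not

The phantom generates cohorts of striatal BR images with a known low-rank
covariance structure in a 32×48×32 template (1 mm voxels) holding two
disjoint axis-aligned ellipsoids: a "putamen" elongated along the
anteroposterior axis (2053 voxels) and a "caudate + ventral striatum"
elongated along the inferosuperior axis (1449 voxels).  Axis-aligned
ellipsoids are the simplest geometry supporting directional gradients.  Left
and right hemispheres share the template (mirror copies), so per-ROI voxel
counts match across sides by construction.

Planted patterns over one ROI are Gram–Schmidt orthonormalized in order from:
a positive constant (kept first so it stays all-positive, like the empirical
first component of striatal data), mean-centered linear ramps along the AP
and IS axes, a ventral–dorsal diagonal ramp (AP+IS direction; requesting it
together with both pure ramps is rejected as linearly dependent), and
deterministic pseudo-random noise textures.

Cohort defaults (the package's study conditions): 40 subjects, disease
duration uniform on 0–16 years, baseline BR 2.0, iid Gaussian voxel noise
SD 0.1 (5 % of baseline) clipped at zero because BR is a nonnegative ratio
(clipping is negligible at these settings).  Pattern scores are mutually
independent: the global pattern's score decreases with aDD
(s₁ = 30 − 1.5·aDD + ε, ε SD 1.0) and the remaining patterns carry
independent variance with well-separated SDs (4.0, 2.4, then 1.2).
Independence with distinct variances is an *identifiability condition*, not
a convenience: PCA diagonalizes the covariance, so planted patterns are
recoverable only when their score covariance is (near) diagonal, and
finite-sample score correlations of order 1/√N rotate patterns whose
variances are closer than ~√(var_i·var_j)/N⁻¹ᐟ².  At N = 40 the two-pattern
configuration recovers both patterns at |cosine| ≥ 0.95 in ≥ 90 % of seeds;
recovering four patterns simultaneously at that tolerance needs N ≈ 160.
The lateralized motor score is generated *from* patterns 1 and 3
(LMS = 11 − 0.25·s₁ + 0.4·s₃ + ε, ε SD 0.2); the clinical table stores it
decomposed into seven integer 0–4 items (the continuous latent value is
returned in the truth object).  The worse hemisphere reuses the better-side
basis with every pattern score shifted by +1.5, emulating a more progressed
version of the same patterns; the worse-side LMS follows through the
coupling and is floored at the better-side value.

Not emulated: realistic anatomy, partial-volume and resolution effects,
tracer kinetics, registration error, non-Gaussian or spatially correlated
noise.  Passing tests therefore demonstrate the *numerics and statistics* of
the pipeline under a faithful low-rank generative model, not robustness to
real-data artifacts.

## Numerical choices

- Voxel-matrix column order is lexicographic over (i, j, k) template
  indices — reproducible across runs and languages.
- Coordinate descent warm-starts along the penalty grid from λ_max down;
  a coefficient left at the subgradient boundary with a float-epsilon
  magnitude is snapped to exact zero (threshold 1e−10·λ relative to the
  column norm), so "intercept-only at λ_max" is exact.
- Inside cross-validation a zero-variance training column gets unit scale
  instead of being dropped (its coefficient is necessarily zero), keeping
  column indices aligned across splits; the public `standardize` drops
  constant columns with a warning.
- The one-predictor mean-BR reference falls back to the intercept-only fit
  when the training predictor is constant.
- Degenerate inputs: constant voxel matrices and all-constant designs are
  rejected; λ_max = 0 yields an all-zero grid with a warning; an all-zero
  weight map projects to zero with a warning and a zero normalization
  factor.
- Image files are written as float64 NIfTI-1, so value round-trips are
  lossless.

## Design choices on genuinely open points

- **p-values of fit coefficients** are computed by an ordinary
  least-squares refit restricted to the active set of the full-data fit at
  λ_min (two-sided t-tests), reported next to the CV mean/SD of each
  coefficient, with the method recorded in the output metadata.
  Post-selection refit is the simplest defensible convention; these p-values
  do not account for the selection step.
- **λ_min over-selection.**  Minimizing cross-validated MSE is known *not*
  to be model-selection consistent: the test-error cost of retaining a null
  input and the shrinkage cost of excluding it are the same order, so λ_min
  models typically keep small nonzero coefficients on uninformative inputs.
  The package reports coefficient stability and p-values precisely so that
  weakly supported terms can be recognized; sparsity-oriented users should
  apply a stricter rule (e.g. one-SE) downstream.
- **Side-assignment ties** default to the right body side (visible warning).
- **Subgroup presets** follow the disease-stage convention: mixed healthy
  controls + PD with DD ≤ 2; early PD (DD ≤ 3); moderate PD (DD ≥ 4); with
  an optional exclusion of agonist-ON subjects for postsynaptic-tracer
  analyses.
- **Reduced CV profile.**  The pipeline default is 100 splits (the full
  protocol of 500 splits is a config choice); the sampling error of the
  reported MSE means scales as 1/√n_splits, and 100 splits already puts it
  well below the between-model differences of interest at these problem
  sizes.  Test-suite simulations use 20-seed batches of 40-subject cohorts
  at the 100-split profile.

## Known limitations

- Inputs must be in template space; no registration is provided or checked
  beyond grid-shape validation.
- The linear model is appropriate only after linearizing the outcome (hence
  aDD); other metrics may need their own transformation.
- PCA pattern recovery requires uncorrelated planted expressions and
  adequate N (see above); real cohorts where pattern expressions co-vary
  will yield rotated mixtures, which remain valid *predictive* inputs but
  complicate one-to-one pattern interpretation.
- Estimator maps inherit the sign and scale conventions of the fit; they
  are comparable across models only after the stated normalization.
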