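# Methods

## Model and procedure

`mslight` maps *local diagnostic information*: the degree to which small
spherical neighborhoods of voxel intensities separate patients from
controls. The unit of analysis is a searchlight — all voxels within
Euclidean distance r (in voxels) of a center, r = 3 by default (123 voxels
untruncated). Searchlights are intersected with the search space of the
current analysis, so near a boundary they shrink rather than mix tissue
classes; a center whose searchlight contains only itself is still mapped.

Per searchlight, the N×V matrix of preprocessed subject intensities is
scored by leave-one-out cross-validation: N folds, each training a linear
soft-margin SVM on N−1 rows and predicting the held-out subject, so every
subject is predicted exactly once. The reported statistic is the balanced
accuracy, 100·(sensitivity + specificity)/2, which is insensitive to the
unequal group sizes (41 vs 26 by default). The test row never enters
training; note however that the default between-subject z-transform is
computed over all subjects (see *Preprocessing order*), matching the
original processing order at the cost of a mild, accuracy-independent
leakage. A strict mode (`fold_z=True` in `loo_cv`/`map_searchlights`)
re-standardizes each fold from its training rows only.

### Classifier

The classifier is an L2-regularized squared-hinge linear SVM with
penalized intercept (liblinear via scikit-learn's `LinearSVC`), cost
C = 1. This is the Newton-SVM family of formulations: minimizing
½(‖w‖² + b²) + C·Σ max(0, 1 − yᵢ(w·xᵢ + b))², which replaces the hinge by
its square and makes the objective smooth. C trades classifier complexity
against non-separable patterns; it is exposed as configuration but fixed
by default, since auto-tuning schemes are approximations that cost
determinism. Fitting is deterministic given the data (fixed internal
permutation seed, tol 10⁻⁴). Decision-value ties (w·x + b = 0) are labeled
control — the conservative direction — which pins down determinism
completely.

### Preprocessing order

The chain is fixed: (1) within-subject standardization — z-scoring the
image over the brain mask; the formula is a design choice, chosen as the
minimal transform removing global scale/offset (e.g. coil loading)
differences; (2) for the *corrected* variant only, voxel-wise OLS
residualization of the N subject intensities on that voxel's three local
displacement components plus an intercept; residuals are exactly
orthogonal to the regressors, so no linearly deformation-explained
variance survives; rank-deficient designs fall back to the minimum-norm
solution (residuals remain the projection complement) and are counted in
the log; (3) between-subject z-transform per voxel to mean 0, SD 1.
Sample SDs use the unbiased N−1 denominator everywhere. Zero-variance
voxels are set to 0 for all subjects and logged. "Local deformation
parameters" are the three displacement components at the voxel itself;
the Jacobian determinant could be added as a fourth regressor but is not
by default, keeping the regressor count far below N.

The t-contrast used in cluster summaries (pooled-variance two-sample t,
N−2 df, patients minus controls) is computed on the same preprocessed data
variant that fed the classifier. The z-transform is a per-voxel affine
map, so t-values are unchanged by it; standardization and confound
regression do affect them, which is intended — the contrast should
describe the data the classifier saw.

### Significance machinery

Each center's 2×2 confusion table (true class × predicted class) is tested
with the Pearson χ² statistic, 1 df, upper tail. This is a deliberate,
documented choice among χ²-based formulations; it reproduces the expected
tail behavior (sensitivity 39/41 with specificity 26/26 at N = 67 gives
χ² ≈ 59.2, p ≈ 1.4·10⁻¹⁴). The statistic is sign-blind, so significance
masks additionally require the center's accuracy to exceed 50%: only
above-chance separability counts as diagnostic information. Degenerate
margins (a class never present or never predicted) give p = 1.

Family-wise error is controlled by Bonferroni over the m centers of the
analyzed space — each (space, variant) analysis corrects within itself.
Per-analysis threshold regimes mirror the original reporting scheme:
lesion/uncorrected uses FWE 0.05 plus a cluster-size criterion k = 5;
lesion/corrected and the uncorrected normal-appearing analyses use FWE
0.05 alone; the corrected normal-appearing analyses use FWE 0.1 and
additionally report uncorrected p < 0.001 trends. "Neighboring" significant
centers default to 26-connectivity (6 and 18 are supported); the choice
only matters for sparse significance masks. Cluster summaries aggregate
the union of the (truncated) searchlights of all cluster centers; Vox\*%
is the share of those voxels with two-sided pooled-t p below 0.001, Mn t
their mean t. Peak ties are broken toward the lexicographically smallest
voxel coordinate. Reported coordinates are voxel indices (0-based)
converted to mm through the diagonal voxel-size affine.

The lesion-presence bound, 100·(n_carriers/n_patients + 1)/2, assumes
lesion-free controls (specificity 1) and sensitivity limited by carrier
prevalence: 19/41 → 73%, 13/41 → 66% after whole-percent rounding.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not anatomy. Templates are nested ellipsoids — brain envelope,
grey-matter shell, white-matter core — with seeds jittering the semi-axes
a few percent; construction fails if the core cannot contain a radius-3
searchlight or any axis is under 16 voxels. Default grid 24³ at 2 mm
isotropic.

Default study conditions (all overridable):

| parameter | default | meaning |
|---|---|---|
| n_ms / n_hc | 41 / 26 | group sizes of the emulated study |
| tissue means | WM 1.0, GM 0.8, bg 0 | arbitrary units; later standardized away |
| noise_sd | 0.2 | i.i.d. Gaussian intensity noise in-brain |
| lesion site | deepest WM voxel, radius 4 mm | ellipsoid in mm, converted per-axis to voxels |
| presence probability | 19/41 | per-patient Bernoulli carriage |
| lesion delta | +1.0 | strong hyperintensity (≈5 noise SDs) |
| nawm_delta / nagm_delta | +0.06 / −0.06 | subtle distributed shifts, patients only |
| deformation field | GRF, SD 0.5 mm, smoothing σ=2 vox | per component |
| deformation_group_shift | 0.5 mm | mean offset of component 1 in patient WM |

The lesion delta is set well above the noise floor because the planted
site must be recoverable at carrier prevalence ~46%: non-carrier patients
are indistinguishable from controls at the site, capping sensitivity near
the lesion-presence bound, with the distributed NAWM shift contributing
the remainder. The NAWM/NAGM deltas (0.3 noise SDs per voxel) are
individually invisible but detectable multivariately across a searchlight
— the regime of interest. Distributed effects are uniform offsets over
configurable region masks (default: the whole tissue template); no
spatially varying random effect field is modeled. `EffectConfig.null()`
zeroes every group effect while keeping lesion geometry and carriage, so
null cohorts retain a non-empty lesion search space for calibration
studies.

What the generator does **not** model: anatomy, bias fields, partial
volume, lesion shape/size distributions, registration error, k-space
artifacts. Passing tests therefore demonstrate correctness of the
machinery and its statistical calibration under the stated generative
assumptions — not performance on clinical images, whose accuracies are
not reproducible from synthetic data.

## Numerical and design notes

- All randomness flows through `numpy` `SeedSequence`; subject seeds are
  spawned from the master seed, so cohorts replay bit-identically and are
  independent of subject count ordering.
- LOO cross-validation with a margin classifier is slightly pessimistic
  under the null at moderate N (removing one subject tilts the boundary
  against its class); at the default N = 67 the null mean balanced
  accuracy sits around 48–50%. Tests assert calibration bands accordingly
  and never expect above-chance null means.
- Problem sizes in tests and the acceptance script (24³ grids; the lesion
  space of the single-site configuration for replicate studies; 10
  recovery and 20–40 null replicates) were chosen to make the Monte-Carlo
  assertions sharp at desk scale; the methods scale unchanged to larger
  grids and spaces.
- TSV outputs use fixed float formatting, making identical runs
  byte-identical; accuracies are stored at full precision and rounded to
  whole percent only in reported tables.
- Voxels lesioned in some subject but outside both tissue templates stay
  in the lesion search space: the lesion analysis covers all lesioned
  tissue. The group lesion mask is intersected with the brain mask.
- Known limitations: Bonferroni is the only multiplicity control (no
  permutation FWE/FDR/TFCE); linear kernels only; the full-sample
  z-transform default is a documented, deliberate fidelity choice.
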