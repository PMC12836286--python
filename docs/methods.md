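# Methods

This note documents the models, conventions and numerical choices in
`noderad`, in the spirit of a statistical software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The prediction problem

Each lymph node contoured on a CT-like volume is to be classified as
benign or malignant. Two feature sets are compared:

- **conventional56** — 56 features computed from the node's own voxels;
- **spatial61** — the same 56 plus 5 lymphatic spatial features that
  encode where the node sits relative to the primary tumor.

The unit of prediction is the node; the unit of data splitting is the
patient, because nodes of one patient share anatomy, scanner and tumor
biology and would leak information across folds if split naively.

## 2. Conventional features

### Intensity (9)

Minimum, maximum, mean, median, standard deviation, sum, skewness,
kurtosis, variance of in-mask HU values. Moments are population
(biased) moments; kurtosis is excess (Fisher) kurtosis. A zero-variance
region reports 0 for standard deviation, skewness and kurtosis — the
sample formulas would be undefined for tiny regions, and 0 is the
natural "no asymmetry / no tailedness" value.

### Geometry (7)

Volume (voxel count × voxel volume), major and minor diameter,
eccentricity √(1 − λ₃/λ₁), elongation √(λ₂/λ₁), axis-aligned physical
bounding-box volume, and surface area as total exposed voxel-face area.
λ₁ ≥ λ₂ ≥ λ₃ are eigenvalues of the population covariance of in-mask
voxel-center physical coordinates, and axis lengths are 4·√λ (the
continuous-ellipsoid convention). The surface-area definition is the
voxel-face (not meshed) surface: exact, fast, and consistent with the
binary mask representation. A feature named for "elongation
orientation" is realized as the single scalar elongation; reporting an
orientation angle would break the fixed count of seven scalar
features.

### Discretization

Texture matrices need integer gray levels. We use equal-width binning
with a fixed count of 32 bins spanning the in-mask min–max range; the
maximum maps to the top level and a constant region maps to level 1.
Fixed bin count (rather than fixed bin width) bounds every matrix at
32 levels regardless of HU range, which keeps the feature scales
comparable across nodes. The bin count is a parameter (`n_bins`) of the
extractor.

### Texture (40)

All matrices are 3D and mask-restricted.

- **GLCM (8):** energy, contrast, correlation, homogeneity (inverse
  difference moment), entropy (log₂), dissimilarity, cluster shade,
  cluster prominence. Co-occurrences are accumulated at distance 1
  along the 13 unique 3D directions; each pair is counted in both
  orders (symmetric matrix), each per-direction matrix is normalized to
  sum 1, features are computed per direction and then averaged
  (feature-wise averaging, not matrix merging). Directions with no
  valid pair are skipped; a region with no pair in any direction
  (single voxel) falls back to energy 1, all other features 0, with a
  log warning. Correlation of a single-level matrix (zero marginal
  variance) is reported as 0.
- **GLRLM (11):** the classic run-length set (SRE, LRE, GLN, RLN, RP,
  LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE), runs being maximal
  same-level in-mask streaks along each of the 13 directions, averaged
  feature-wise as above. Run lengths are computed by a shift-based
  dynamic program, validated against a pure-Python enumerator.
- **GLSZM (16):** zones are 26-connected components of equal gray
  level (via `scipy.ndimage.label`); the matrix is direction-free.
- **NGTDM (5):** coarseness, contrast, busyness, complexity, strength
  over the 26-neighbourhood; a voxel contributes only if at least one
  neighbour is in-mask. The coarseness denominator is guarded at 1e-6,
  so a perfectly homogeneous region reports coarseness 1e6. With a
  single occupied gray level, contrast, busyness and strength are 0 by
  convention.

The partition 8 + 11 + 16 + 5 = 40 is this package's documented
convention for "texture features from the four matrices"; the manifest
(`feature_manifest.json`, written next to extracted CSVs) lists all
names in canonical order.

## 3. Spatial features

Four integer codes (primary tumor type 1–5, nodal level 1–6 with
clinical sub-levels IIa/IIb/Va/Vb mapping to their parent, node
laterality 0/1, tumor laterality 0/1/2 with 2 = midline/NA), plus the
Euclidean distance in mm between the unweighted mask centroids of node
and tumor. Centroids are mask-geometric, not intensity-weighted. The
integer codes are fed to the classifier as plain numbers: the Gaussian
kernel's nonlinear mapping treats them closer to nominal categories
than an ordinal scale would suggest; an opt-in one-hot expansion
(`one_hot_spatial`) exists but the integer encoding is the default,
tested path.

## 4. Preprocessing inside cross-validation

Within each CV iteration, in order:

1. **Min-Max scaling** fitted on the raw training rows only
   (per-feature min/max), applied to train and test. Test values
   outside the training range are *not* clipped — a clipped test set
   would silently import training-range information into the
   evaluation. Constant training columns map to 0.
2. **SMOTE** on the scaled training rows: synthetic minority samples
   x_i + u·(x_nn − x_i), u ~ U(0,1), x_nn among the k = 5 nearest
   minority neighbours (Euclidean), drawn until exact class balance.
   k is reduced with a warning when the minority class is smaller than
   k + 1. Scaling precedes SMOTE because nearest-neighbour geometry is
   only meaningful on a common scale. Categorically coded spatial
   features are interpolated like any numeric feature — a documented
   caveat of the integer encoding.

Synthetic rows are flagged and never leave the training side; the
pipeline asserts this on every run.

## 5. The classifier

Soft-margin SVM with Gaussian kernel exp(−‖x−y‖²/2σ²), parameterized
by the width σ (the tuning grid operates on σ directly, not on γ).
The dual problem is solved by simplified SMO: sweep the first working
index over all samples, draw the partner uniformly at random (seeded),
solve the two-variable subproblem analytically, clip to the box
[0, C]. Sweeps continue until `max_passes` consecutive sweeps produce
no update at KKT tolerance `tol` (default 1e-3). After convergence the
bias is recomputed from the multipliers: the mean margin equation over
free support vectors, or the midpoint of the KKT-feasible interval
when every multiplier is at a bound (the running bias of simplified
SMO is not guaranteed to be KKT-consistent in that case). On small
instances the solver's dual objective matches a brute-force QP oracle
(SLSQP plus an exact active-set polish) to better than 1e-6 relative.

Probabilities come from Platt scaling — p(y=1|s) = 1/(1 + exp(As + B))
fitted on the training decision scores by Newton iterations with
Platt's smoothed targets — and the operating threshold is 0.5.
Duplicating the training set leaves the decision function unchanged
only when no multiplier saturates at C (duplication is equivalent to
doubling C otherwise); the tests exercise the interior-solution case.

## 6. Nested cross-validation

Outer: patients are shuffled (seeded) and dealt into 5 folds whose
sizes differ by at most one; all nodes of a patient share its fold.
Inner: the 4 remaining folds are re-split by patient into 4 inner
folds; each (C, σ) grid point is scored by mean inner validation
accuracy at threshold 0.5, with ties broken toward the smallest C,
then the smallest σ. The final per-iteration model is trained on the
full (scaled, SMOTE-balanced) outer-training set with the selected
hyperparameters. Inner k = 4 preserves the natural 5-fold split of the
training side. The default grid is C ∈ {2⁻³…2⁷}, σ ∈ {2⁻⁴…2⁴}; the
acceptance runs use small or singleton grids so that the full
experiment fits in minutes on one CPU — the contract being tested
(direction of the spatial-feature effect) does not depend on dense
tuning.

The two model arms (conventional56, spatial61) always share the same
fold assignment and seeds; the comparison report echoes the fold hash
of both arms to prove it.

## 7. Evaluation statistics

- Confusion metrics at threshold 0.5; PPV/NPV with an empty
  denominator are NaN with a warning, never silently 0.
- AUC is the Mann–Whitney statistic with half credit for ties, which
  equals the trapezoidal area under the empirical ROC exactly.
- Clopper–Pearson exact intervals via beta quantiles. SEN/SPE
  intervals use their class-specific denominators by default;
  `pooled_n_cis=True` switches to the pooled node count (some reports
  quote interval widths consistent with the pooled n).
- BCa bootstrap for the AUC: nodes resampled with replacement
  (resamples missing a class are redrawn), z₀ from the fraction of
  bootstrap AUCs below the point estimate, acceleration from jackknife
  AUCs; a degenerate bootstrap distribution collapses the interval to
  the point estimate. The resampling unit is the node; a patient-level
  cluster bootstrap would widen intervals and can be added by callers
  who need it.
- DeLong's test from placement values with midrank ties; zero variance
  with zero AUC difference gives p = 1, zero variance with a nonzero
  difference is flagged degenerate (NaN) rather than reported as p = 0.
- The paired accuracy comparison is a paired t-test on per-node 0/1
  correctness indicators. Fold-level pairing (5 accuracies) could not
  produce the very small p-values such comparisons are known to show
  at ~1400 nodes; per-node pairing is the implemented default.

## 8. The phantom generator

The generator emulates the *statistical structure* the pipeline
assumes, not anatomy. A 96×96×96 voxel frame at 1 mm spacing holds a
soft-tissue background (40 ± 2 HU), one ellipsoidal tumor at a
site-specific canonical location (base of tongue, tonsil, oropharynx,
larynx, hypopharynx; default mix 34/32/3/28/3%), and Poisson(7.2,
truncated ≥ 1) ellipsoidal nodes at level-specific canonical centers
left/right of the midline with 2.5 mm jitter. Texture is correlated
Gaussian noise (white noise smoothed at σ = 1.2 voxels) rescaled to a
class-dependent amplitude: 8 HU for benign, 14 HU for malignant nodes,
each times a per-node lognormal heterogeneity multiplier. ROIs are
kept pairwise disjoint by re-jittering and, as a last resort, carving.

Malignancy is drawn from a logistic model over six attributes:
intercept −1.38, distance −0.06/mm, laterality concordance +1.4, a
level-affinity profile (II and III most prone) scaled by 1.0, size
+0.6 per 1000 mm³, heterogeneity +1.0 per relative noise-sd excess,
plus a fixed per-site offset (base of tongue most prone). The
intercept was calibrated once, by bisection on the expected probability
over the attribute distribution, to the target prevalence 270/1389 ≈
0.194; the remaining weights are fixed design choices giving each
attribute a clinically plausible direction and a detectable but not
dominating effect. Labels feed back into rendering: malignant nodes
get 1.25× larger axes and the higher noise amplitude, so conventional
features also carry class signal.

Attribute sampling (`sample_cohort_metadata`) is separated from voxel
rendering (`render_patient`) and each uses its own seeded substream,
so statistical checks on the generative model can run on thousands of
nodes without touching image data, and individual patients can be
re-rendered independently.

**What a green test establishes — and what it does not.** The phantom
has real class signal in both imaging and spatial features by
construction, so end-to-end tests establish that the pipeline recovers
signal that exists, without leakage, and that the spatial arm adds
discrimination when spatial structure carries independent information.
It does not establish clinical performance: phantom texture is
stationary Gaussian noise, node shapes are ellipsoids, there is no
partial-volume effect, no contouring variability, and no correlation
between nodes of a patient beyond shared geometry.

## 9. Degenerate inputs and tolerances

- Single-voxel ROIs: geometry diameters 0; GLCM falls back to its
  degenerate convention; GLRLM/GLSZM treat it as one run/zone; NGTDM
  (no neighbour) falls back with a warning.
- Masks are validated non-empty at construction; empty-mask operations
  are therefore unrepresentable rather than silently zero.
- SMO: tol 1e-3 and max_passes 5 for pipeline fits (accuracy-level
  work); tests that compare against the QP oracle tighten tol to 1e-8.
- KKT audits run at tolerance 1e-3: α=0 ⇒ y·f ≥ 1−tol; 0<α<C ⇒
  |y·f − 1| ≤ tol; α=C ⇒ y·f ≤ 1+tol, with Σαᵢyᵢ = 0 to 1e-9.
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator(PCG64)`; identical seeds give byte-identical
  cohorts, folds, SMOTE draws and SMO runs.

## 10. Known limitations

- No resampling to isotropic grids and no filtered-image features; the
  extractor assumes the mask and volume share one grid.
- Integer-coded categorical features are interpolated by SMOTE and
  scaled by Min-Max like continuous ones.
- The BCa interval treats nodes as exchangeable units, ignoring
  within-patient clustering.
- The phantom's canonical geometry is a single rigid frame; it cannot
  probe robustness to anatomical variability or imaging protocol
  differences.
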