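# Methods

This note documents the models and numerical choices behind `lenshape`:
what each statistic assumes, which parameters matter, what the synthetic
generators do and do not emulate, and where the design was genuinely open.

## Shape metrics from label volumes

A segmented lens is a set of foreground voxels in a 3D integer label grid
with physical spacing (mm). Voxel centers sit at `(index + 0.5) × spacing`;
axis 0/1/2 are fixed as anterior–posterior / dorso-ventral / naso-temporal.

**Eigenvalue metrics.** Each foreground voxel center is an equally weighted
point (segmentations are binary; no grey-level weighting). The population
covariance of those points has eigenvalues `l1 ≥ l2 ≥ l3` (mm²); for a
uniform solid ellipsoid with semi-axes `(a, b, c)` the covariance is
exactly `diag(a², b², c²)/5`, which is the analytic oracle used throughout
the tests. The metrics are computed on the raw (not square-rooted)
eigenvalues:

* anisotropy `= 1 − l3/l1`, flatness `= l3/l2`, elongation `= l2/l1`.

This is the unique common convention for which a sphere scores (0, 1, 1)
and the identity `anisotropy = 1 − flatness × elongation` holds. Square-
rooted eigenvalues would change magnitudes on non-spheres but not the
sphere calibration; the raw convention is fixed here and documented so
that values are comparable across runs. Ties in the eigenvalue sort are
broken arbitrarily — the metrics depend only on the sorted values.

**Degenerate labels.** Fewer than 4 voxels, or collinear/coplanar voxels,
raise a hard error rather than propagating NaN: `l3 = 0` is reported with
a `degenerate` flag by `covariance_eigenvalues`, and
`compute_shape_metrics` refuses to divide by it.

**Surface area and sphericity.** Sphericity is `π^(1/3)(6V)^(2/3)/A`, with
`V` the foreground voxel count times the voxel volume, and `A` the area of
a closed isosurface mesh (marching cubes at level 0.5 on the binarized
label, padded by one voxel so boundary-touching labels still close). The
raw marching-cubes surface of a binary mask is a staircase whose area
overestimates a sphere's by roughly 6–10% (a naive voxel-face surface is
far worse, ≈ +50%), which would bias sphericity low. The mesh is therefore
smoothed before measurement with a Taubin filter (a shrinkage-compensated
Laplacian-style smoother; a plain Laplacian filter shrinks a sphere and
would bias area the other way). The default of 20 iterations brings a
radius-40 sphere's area within 1% of `4πr²`; smoothing is exposed as
configuration because measured sphericity magnitudes depend on it, and
any cross-study comparison should hold it fixed. With these defaults a
voxelized sphere scores sphericity ≈ 0.990; the residual deficit is
discretization, not mesh breakage. A computed sphericity above 1.05
raises an internal-consistency error (a broken mesh), and labels with
multiple 26-connected components are reduced to the largest with a
warning.

**Diameters.** The transverse diameter along an anatomical axis is the
maximum caliper extent of the label parallel to that axis (bounding-box
extent in physical units) — the automated analogue of placing a cutting
plane through the rendering where the structure is widest. Left and right
eyes are measured as separate labels and averaged.

## Phylogenetic statistics

**Covariance.** `C[i, j]` is the root-to-MRCA shared path length of tips
i and j, computed by a single post-order sweep. Zero-length terminal
branches are replaced by `1e-8 ×` tree height with a warning so `C` stays
invertible. Tip names are normalized (whitespace → underscore) before
matching tables to trees.

**PGLS with Pagel's λ.** The model is `y = Xβ + ε`,
`ε ~ N(0, σ²V(λ))`, where `V(λ)` multiplies the off-diagonal of `C` by λ.
λ is profiled on a 101-point grid over [0, 1] followed by bounded local
refinement; boundary optima are reported as exactly 0 or 1, and a flat
profile (e.g. a star phylogeny, where λ is unidentifiable) is flagged.
The profile criterion is ML by default, with REML available by flag; the
two differ slightly in λ̂ and the default follows the convention of the
widely used GLS implementations this package was validated against
(`nlme::gls` + `ape::corPagel`, agreement to ~1e-3 in λ̂ and ~1e-4 in
log-likelihood on test fixtures). Categorical predictors use treatment
contrasts with the alphabetically first level as reference unless
overridden. The overall F compares the full model to the intercept-only
model under the full model's `V(λ̂)` — one F per model, df `(p−1, n−p)` —
and `R²_adj` comes from the generalized residual sums of squares.
Missing data are handled by listwise deletion per model.

For ultrametric trees `diag(C)` is constant, so
`V(λ) = λC + (1−λ)hI` shares C's eigenvectors; one eigendecomposition
serves the entire λ grid, making the profile O(np²) per grid point. The
general path (Cholesky per λ) is used for non-ultrametric trees and is
tested to agree with the fast path.

**K_mult.** Multivariate phylogenetic signal is the multivariate
generalization of Blomberg's K:

    K = [ tr(EᵀE) / tr(EᵀC⁻¹E) ] / [ (tr(C) − n/(1ᵀC⁻¹1)) / (n − 1) ]

with `E = X − 1âᵀ` and `â` the GLS (phylogenetic) mean. K ≈ 1 for traits
evolved by Brownian motion on the tree (verified by simulation: mean K =
0.999 ± 0.004 over 5000 replicates across tree shapes; the mean
conditional on a single tree can sit a few percent off 1). Significance
comes from permuting data rows across tips, with the observed statistic
included in the null set, so the attainable p floor is `1/(n_perm+1)`;
the default is 999 permutations and a seed is mandatory in pipeline runs.
With one trait column the statistic reduces to univariate K and matches
`phytools::phylosig` to 1e-6 on test fixtures.

**Non-phylogenetic tests.** Life-stage contrasts use Welch's
unequal-variance t-test (recognizable by its non-integer d.f.). PCA
decomposes the correlation matrix by default (`scale=True`) because the
three shape metrics have very different variances; the covariance option
is exposed. Component signs are arbitrary and fixed per run (largest
loading positive, then anisotropy's PC1 loading negative) purely for
display comparability. The collinearity screen drops the lower-priority
member of any metric pair with |r| above threshold (default 0.9; priority
anisotropy > sphericity > elongation > flatness) — in practice flatness
is removed because it is algebraically `(1 − anisotropy)/elongation`.

## The pipeline

Stages run on a species × life-stage table (one row per species and
stage, produced from per-specimen rows by unweighted averaging with
conflict detection on ecological scores) and a Newick tree. All stages
are pure functions of (table, tree, config); a fixed seed gives
byte-identical JSON reports. Species missing a required stage, ecological
score or diameter are excluded listwise per analysis and the exclusions
are logged; habit levels with fewer than 2 species are dropped with a
warning.

Design choices where the procedure was open:

* Post-hoc comparisons among habit levels are Wald contrasts from the
  full PGLS fit, Holm-corrected at α = 0.05 (Bonferroni switchable), with
  compact letter groupings computed as maximal cliques of the
  non-significance graph.
* Per-environment slopes in the metamorphosis stage come from releveling
  the factor and refitting: the refit intercept is that level's mean
  delta.
* Relative-size residuals for display come from the diameter-only PGLS
  (no ecology term); the ecology term itself is tested by a partial F
  against the diameter-only model under the full model's `V(λ̂)`.
* The diameter model fits raw mm by default (`lens ~ eye`); a
  `log_diameters` switch fits the allometric log–log form.
* Life-stage PC scores (and their ontogenetic differences) come from the
  pooled two-stage PCA; a per-stage PCA would yield non-comparable axes.

## Synthetic data: what it does and does not emulate

**Phantoms** are sphere/ellipsoid/superellipsoid implicit surfaces
voxelized at voxel centers, optionally perturbed by a smooth random
radial field (Gaussian field, σ = 2 voxels, scaled to a requested
amplitude) — a stand-in for segmentation boundary noise. Ground truth
volume (`4πabc/3`) and area (closed forms for spheres/spheroids,
quadrature otherwise) accompany every phantom. They do not emulate CT
texture, staining contrast, or manual-segmentation artifacts, so passing
phantom tests shows geometric correctness of the metric chain, not
robustness to segmentation style.

**Trees** are pure-birth (Yule) simulations rescaled to ultrametric
height 1, tips `sp0001…`.

**Studies** mirror a CT survey of biphasic anurans at its published
sampling scale: 126 species (121 with adult data, 50 with tadpole data,
45 paired, with paired sampling stratified across adult environments so
both are represented), six habit categories, two activity categories.
Tadpole metrics are a baseline plus λ-transformed Brownian deviation plus
i.i.d. noise; adult metrics add a stage-by-environment delta (anisotropy
+0.15 for terrestrial-bound species vs +0.01 for aquatic, sphericity
−0.03 vs −0.01), habit offsets (fossorial adults cancel most of the
terrestrial delta, mirroring their retention of spherical lenses), and
their own phylogenetic deviation. Adult diameters follow
`log lens = −0.75 + 0.90 log eye + habit offset + N(0, 0.05)` with a −5%
offset for aquatic and semiaquatic habits. Metric values are clipped to
[0, 1] with a warning, which slightly truncates tails near the bounds.
Defaults for quantities with no published value (habit frequencies,
baselines, noise SDs, allometry) were chosen once as field-plausible
magnitudes and are all exposed on `StudySpec`; every generating parameter
is returned in the ground-truth record.

Habit is assigned independently of phylogeny by default — deliberately,
so effect-recovery tests are clean. A consequence is that adult trait
matrices carry weak multivariate signal (K_mult small), unlike real
adult data where habit is phylogenetically clumped; the generator is not
intended to reproduce published K values, only calibration behavior
under known conditions.

## Calibration experiments shipped as tests

* Sphere calibration: all four metrics within 0.02 of their sphere values
  on a radius-40 phantom.
* Ellipsoid oracle: eigenvalues within 2% of `diag(a²,b²,c²)/5`;
  implementation covariance equals an independent brute-force summation
  to 1e-9 relative error.
* Engine calibration: PGLS(λ=0) ≡ OLS to 1e-10; λ̂ recovery bias < 0.05
  at 256 tips (200 replicates per true λ ∈ {0, 0.5, 1}); K_mult mean = 1
  within Monte-Carlo CI over 500 Brownian replicates; permutation
  p-values uniform under exchangeable data (KS, α = 0.01); type-I error
  of the 6-level habit F-test at nominal 5% (binomial CI, 1000 Brownian
  null replicates at the 126-species study scale).
* Effect recovery: the metamorphosis stage detects the environment effect
  (one-sided, α = 0.05 — the hypothesis is directional) with the correct
  sign in ≥ 95% of 200 simulated studies under default conditions.

Replicate counts and problem sizes above are the experiment definitions;
the pipeline itself has no scale limits beyond O(n³) linear algebra in
the number of species.

## Known limitations

* Sphericity depends on the smoothing configuration; only values computed
  under the same smoothing are comparable.
* λ̂ for a single trait at n ≲ 100 is noisy (SD ~ 0.1 at n = 256 under
  λ = 0.5) and boundary-attracted; the F-test that plugs in λ̂ is mildly
  anticonservative at small n (~7–8% at n = 64 in simulation).
* The K_mult permutation test conditions on the tree; it does not account
  for tree uncertainty.
* NRRD support covers raw/gzip scalar volumes with embedded spacings;
  detached-data NRRD files are not read.
* No segmentation is performed: inputs are label volumes produced
  elsewhere.
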