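# Methods

This note documents the models, algorithms and numerical choices behind
`growthchart`, in the order the pipeline runs them.

## The problem

During the first two postnatal weeks, mouse brain regions grow at different
rates while their constituent cell types (GABAergic interneurons, microglia)
change density along region-specific trajectories.  Given a labeled atlas
volume, an anatomical ontology, and per-sample tables of detected cell
centroids registered to that atlas, the package produces "growth charts" —
per (region, sample, age, cell type) tables of volume (mm³), counts, and
density (cells/mm³) — plus two inferential procedures: a functional-data
test for changes in the *spatial pattern* of cortical density, and a
Bayesian multilevel model for changes in its *magnitude*.

Because the imaging data behind such a study is not required here, a
first-class synthetic module generates a miniature study with known ground
truth, so every downstream stage is testable end to end.

## Synthetic study generator

**Atlas.** The default label volume is 64×64×32 voxels at 20 µm isotropic
(matching the resolution class of developmental templates).  The cortex is a
6×6 grid of 10×10×10-voxel columnar parcels (36 leaf regions, close to the
37-region cortical parcellations used in practice); column depth follows a
shallow dome plus a small deterministic stagger so region centroids are not
coplanar — this keeps the tensor-spline design matrix full column rank.
Four subcortical blocks sit beneath the slab.  The ontology is three levels:
root → {cortex, subcortex} → leaves.

**Trajectories.** Per (region, cell type) the expected density follows one
of three archetypes: `increase` (linear in age index from baseline to
baseline×effect), `decline_then_stable` (linear decline to the plateau value
at the stabilization age, constant after; default plateau P12), or `stable`.
Defaults: cortical GABAergic cells start near 12,000 cells/mm³ with a ±15%
regional gradient and halve by P12 (the roughly two-fold decline reported
for developing cortex); cortical microglia triple from ~3,000 cells/mm³;
subcortical GABAergic density doubles; subcortical microglia stay at
4,000 cells/mm³.

**Sampling.** One biological sample = one (cell type, age, replicate).  Per
region the cell count is Poisson(density × region volume × f), where f is a
unit-mean lognormal sample factor with CV 0.1 shared across the sample's
regions — a multiplicative between-animal effect matching mean ± s.d.
reporting without claiming a specific biological noise model.  Positions are
uniform within the region (uniform voxel, then uniform within the voxel).
The study seed spawns per-sample child seeds by fixed arithmetic
(seed + sample index), recorded in the manifest, so a study is byte-identical
given its seed.

**Detection.** `ideal` mode reproduces section-based 2D counting exactly:
per (region, compartment) the detected count is the true count divided by
the compartment's conversion factor, rounded half-up, no false positives —
making the 2D→3D conversion invertible to ±factor/2.  `stochastic` mode
thins cells with probability `detection_probability / factor` and adds
uniform false positives (default 50/mm³ of labeled tissue).  Detections are
annotated TP/FP by greedy nearest-neighbour matching against the truth
within 15 µm, each truth cell used at most once.  The matching protocol for
F-scores in real studies is rarely published; this rule is a declared
stand-in.  Sectioning itself is represented only through the detection
probability, not by geometric slicing.

## Quantification

Coordinates are world µm; the voxel of a centroid is the 0-based floor of
(coordinate − origin)/voxel size, with half-open voxels `[k·s, (k+1)·s)` —
cells exactly on the grid's upper boundary are out of grid, assigned
background (id 0) and tallied.  Region volume is voxel count × voxel volume
(µm³ → mm³, 10⁻⁹).  2D counts convert to 3D estimates by the compartment
factor (1.4 cytoplasmic, 1.5 nuclear), kept fractional; density is
count₃D / volume, with zero-volume rows flagged invalid rather than
dividing.  Ontology roll-ups sum counts and volumes over descendants and
recompute density from the sums (never averaged).  Detection quality is the
harmonic-mean F-score 2PR/(P+R) = 2TP/(2TP+FP+FN); the degenerate
TP=FP=FN=0 case is defined as 0 with a warning.

## Cortical flatmap

The synthetic flatmap is a column projection: cortical voxel (i, j, k) maps
to bin (i − i_min, j − j_min), so the AP and azimuth axes are the two
in-plane voxel axes.  Per-bin density uses the bin's true mapped tissue
volume as denominator, keeping flatmap values in cells/mm³ like the growth
chart; bins with no mapped tissue are masked, not zero.  Averaging is the
element-wise mean over samples with the union of masks.  Volume
normalization multiplies by V_age/V_reference exactly as the convention
prints it, storing the factor in the sidecar so it can be inverted; in the
synthetic pipeline the reference defaults to the oldest age's cortical
volume (the toy study has a single fixed geometry, so the factor is 1 and
recorded as such).

## FDA topography test

Each sample's cortical density profile is treated as noisy evaluations of a
smooth function of space at the 36 region centroids (centroids = mean voxel
centers of each region).

- **Basis**: tensor product of clamped 1D B-spline bases, knots uniform
  over the centroid bounding box expanded 5% per side.  Default 3 basis
  functions per axis of degree 2 (27 columns ≤ 36 regions, so the
  unpenalized fit is determined).  A clamped basis of degree d needs at
  least d+1 functions, so 3 per axis forces quadratic; cubic is available
  with n_basis ≥ 4, and a ridge penalty (λ‖c‖²) is available for larger
  bases.  Rows of the design matrix sum to 1 (partition of unity).
- **Fit**: per-sample least squares via LAPACK `lstsq`; rank-deficient
  designs with λ = 0 raise instead of silently pseudo-inverting.
- **FPCA**: principal components of the fitted functions under the true
  function-space inner product.  With Gram matrix G (exact per-axis
  Gauss–Legendre integration, d+1 nodes per knot span, Kronecker product
  across axes) and centered coefficients A, the components are the SVD
  directions of A·L (G = LLᵀ), mapped back by L⁻ᵀ; they are G-orthonormal.
  The component count is the smallest m whose cumulative explained-variance
  ratio reaches 0.99, capped at min(samples − 1, basis size); all-identical
  samples give a 0-component model.
- **Errors and outliers**: each sample is projected onto the retained
  components and reconstructed; its error is the L2 norm of (observed −
  reconstructed) at the region evaluation points.  Outliers are samples at
  or above the empirical 99th percentile of errors (linear-interpolation
  quantile — stated because n is small).
- **Permutation ANOVA**: one-way F on the per-sample errors grouped by age
  ("mean errors across ages" is read as group means of per-sample errors;
  the per-age-mean reading would leave no within-group variance).
  Monte-Carlo p = (1 + #{F* ≥ F})/(1 + n_perm) with 10,000 permutations by
  default (never exactly zero); exhaustive mode enumerates all distinct
  assignments including the identity.  F values are rounded to 12
  significant digits before ≥ comparisons to stabilize enumerations.
  All-equal errors give F = 0, p = 1.
- **Pairwise tests**: |mean difference| statistic per age pair (the
  statistic is not standardized in the literature; the absolute mean
  difference is the simplest exchangeable choice), Benjamini–Hochberg
  step-up across pairs, adjusted p never below raw.

### Known limitation: power against smooth shifts

Because the FPCA is fitted pooled across ages with a 99% variance target,
any age-specific deviation large enough to matter contributes a top-ranked
eigendirection and is *retained* as a component — after which the shifted
samples reconstruct as well as the rest and the errors carry no group
signal.  Simulation confirms this: a rotated-gradient mean shift at 50% of
the between-region SD in one age (n = 6/age) is rejected in only ~5–40% of
replicate studies across realistic noise settings, not ≥90%.  The test is
therefore sensitive to deviations living in the *excluded* variance tail —
fine-scale, non-smooth, or heteroscedastic structure — rather than to
dominant smooth mean shifts; magnitude shifts are the multilevel model's
job.  The null calibration of the permutation p is exact regardless (label
exchangeability), which the test suite verifies.

## Bayesian multilevel model

For one cell type, observation i (one region of one sample):

    y_i = μ_age(i) + u_region(i) + v_sample(i) + ε_i
    u_r ~ N(0, σ²_region),  v_s ~ N(0, σ²_sample),  ε ~ N(0, σ²_resid)

Age is an unordered categorical fixed effect (ordered only for the trend
contrast).  Priors are weakly informative and conjugate: μ_a ~ N(0,
(10·sd(y))²), Inverse-Gamma(2, sd(y)²) on each variance component — chosen
for closed-form Gibbs updates, not to match any particular PPL's defaults,
so correctness is established by parameter recovery on data simulated from
the model rather than numerical agreement with another sampler.

The sampler is Gibbs with two exact *location-interweaving* moves per
sweep: shifting (μ + c, u − c) leaves the likelihood invariant, so c is
sampled from its conditional under the priors and applied — once globally
for the region block, and once per age for the sample block (samples are
nested in ages, giving each age its own flat ridge).  Both moves preserve
the posterior exactly and remove the slow directions that make plain Gibbs
mix poorly; with them, split R-hat < 1.01 is reached at 2 chains × 500
retained draws on the default study.  Defaults are 2 chains × 4000
iterations (2000 warmup), no thinning; variance updates are conjugate
inverse-gamma draws.

Summaries: the global age effect is the linear-trend contrast with centered
integer weights over the ordered ages (a single Est./CI summary of "all age
means equal" is not a standard contrast; the weights are exposed so
last-vs-first or any custom contrast can be requested).  Pairwise contrasts
are μ_a − μ_b draws summarized by posterior mean, 95% equal-tailed CI, and
95% HPD (the narrowest window containing ⌊0.95·n⌋ sorted draws);
significance flags mean the HPD excludes 0.  Split R-hat (via ArviZ) is
reported per parameter; a constant parameter reports 1 by convention, and
any R-hat ≥ 1.01 flags the fit non-converged.

## Pipeline and reproducibility

Stages run in dependency order (simulate → quantify → flatmap → fda → mlm →
report); each writes plain-text artifacts (CSV/JSON/YAML; NIfTI for the
label volume, gzipped with a zeroed timestamp so reruns are byte-identical)
stamped with the config hash and seed.  Completed stages are skipped unless
forced.  Ages are explicit ordered labels ("P4".."P14"), never sorted
lexicographically.  All randomness descends from the single study seed.

## Problem sizes used in tests

The test suite exercises the default miniature study (40 regions, 6 ages ×
2–4 samples/age, ~10⁵ cells), 500 replicate null studies × 1000
permutations for type-I calibration, 100 replicate shifted studies for the
power experiment, and 50 reduced-length multilevel fits (2 chains × 1000
retained draws) for HPD coverage — sizes chosen so the full suite runs in a
few minutes on one CPU while keeping every statistical check at
interpretable resolution.

## Limitations

- The generator places cells uniformly within regions; no laminar or
  columnar microstructure, soma shapes, or registration deformation.
  Passing recovery tests therefore validates the counting/conversion
  machinery, not robustness to registration error.
- The flatmap is a column projection of a synthetic slab, not a
  curvature-preserving projection of a real cortical sheet.
- The detection-error model is a thinning/false-positive abstraction; the
  reported F-scores characterize that abstraction, not a pixel classifier.
- The FDA test's insensitivity to retained smooth shifts, discussed above.
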