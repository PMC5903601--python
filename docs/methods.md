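# Methods

This note documents the models implemented by `neurosep`, the
assumptions behind them, the numerical choices made where the design
was open, and what the synthetic-data tests do and do not demonstrate.

## Generative picture

The functional pipeline assumes a *group spatial-source model*: all
subjects in a study share C spatial sources (rows of S, one weight per
brain voxel) and differ only in their time courses. Subject i's
(preprocessed, row-centered) T×V series is

    X^i ≈ A_i S,          A_i ∈ ℝ^{T×C},  S ∈ ℝ^{C×V}.

The structural pipeline assumes group-discriminative information lives
in local *texture* — the joint arrangement of intensities in small
(5×5×5) neighbourhoods — rather than in global intensity statistics,
which the z-normalization step deliberately removes.

## Preprocessing (cohort_io)

Only the tail of a standard preprocessing chain is in scope: Gaussian
smoothing of functional volumes (default FWHM 8 mm, converted to a
kernel sigma of fwhm/(2√(2 ln 2)) voxels per axis using the voxel
size) and z-normalization of every 3D volume to mean 0 / SD 1. Motion
correction, co-registration and non-linear template normalization are
assumed done by external tools; inputs are spatially normalized
NIfTI-1 files.

Subjects with different series lengths are brought to the cohort
minimum T by truncation (linear resampling onto T equally spaced
points is available as a config option). Nothing in the model fixes
this choice; fixed-length time-course features require *some*
convention, and truncation is the one that never interpolates data.

Voxel ordering is fixed once: C order of the (X, Y, Z) array. Every
column index in the package (spatial maps, local-covariance regions)
refers to this order.

## Structural texture (structural_texture)

All 5×5×5 patches (stride 1) of the training volumes are sampled, up
to a budget of 100 000 patches per cohort (seeded uniform subsample;
the full patch set of one standard scan alone is ~437 k rows, and the
filters stabilize well below the budget). A single-layer sparse
autoencoder with k hidden units (default 3) is fit by L-BFGS on the
exact gradient of

    J = 1/(2|D|) Σ ‖x − x̂‖² + β Σ_j KL(ρ‖ρ̂_j) + λ(‖θ₁‖² + ‖θ₂‖²).

Numerical choices: weights initialized uniformly in ±√(6/(n+k)) from
a fixed seed, biases at zero; mean activations clamped to
[1e−8, 1−1e−8] so the KL term stays finite; stop at gradient ∞-norm
below 1e−5 or 400 iterations. Defaults β = 1, λ = 1e−4, ρ = 0.05; an
internal 5-fold CV over β ∈ {0.1, 1, 3}, λ ∈ {1e−4, 1e−3},
ρ ∈ {0.01, 0.05} (held-out reconstruction error) is available.

Each encoding row, reshaped to 5×5×5, is a texture filter. Features
are valid correlation + sigmoid over the whole volume, max-pooled over
disjoint 5×5×5 blocks, concatenated filter-major. Two pooling-grid
conventions exist: the default `ceil` mode keeps trailing partial
blocks as their own cells (exhaustive tiling); the `round` mode uses
round(dim/5) cells per axis with the trailing cell cropped/extended,
which reproduces the conventional 15×18×13 grid (and hence the
10 530-length vector) for a 79×95×68 template-space scan. For that
scan valid convolution gives 75×91×64 outputs; descriptions quoting 74
for the first axis are treated as a typo since the other two axes
match valid convolution exactly.

## Two-step PCA and back-reconstruction (fmri_reduction)

Subject-level PCA eigendecomposes the T×T Gram matrix of the
row-centered series (the smaller dimension; V×V is never formed) and
keeps the smallest T_red capturing 99 % of the variance. The reduced
matrices are stacked over subjects (temporal concatenation) and a
group-level PCA keeps K rows the same way. Row-centering at both
levels is our choice (the convention of standard group-ICA toolboxes);
the removed means are stored so reconstruction is exact. If a backend
asks for more components than K, K is raised to C with a warning.

Back-reconstruction inverts the two reductions:

    A_i = U_i⁺ (F⁺)_i A.

One subtlety is deliberate: `(F⁺)_i` is the *subject-i row block of
the pseudo-inverse of the whole group operator F*, not the
pseudo-inverse of the isolated block F_i. Because F has orthonormal
rows, F⁺ = Fᵀ is the exact inverse on the retained subspace, and the
subject block of it maps group components back onto subject i's
reduced rows exactly; the isolated blocks of F are not orthonormal,
so inverting them separately introduces avoidable cross-subject
leakage. With full variance retained (var_frac ≈ 1) on noiseless
rank-C data the round trip X^i → PCA → separation → A_i S reproduces
X^i to machine precision, and the test suite holds it to 1e−6.

Holdout subjects are never part of the group PCA; their time courses
come from least-squares projection onto the fixed maps,
A_i = X^i S⁺. This train-only policy is stricter than strictly
necessary for a descriptive analysis but is the only defensible one
for a predictive study.

## Source separation (source_separation)

Four backends factor the representative matrix X (K×V):

* **pca** — identity: S is the first C rows of X; A the matching
  columns of I. Baseline and the exactness reference.
* **kpca** — RBF kernel over voxel columns,
  Σ(i,j) = exp(−‖x_i−x_j‖²/2σ²), double-centered; top-C eigenvectors
  (unit norm) are the maps, A is the least-squares projection of X
  onto them. The V×V kernel is dense, so a feasibility guard rejects
  V above a configurable limit (default 20 000). In the wide-kernel
  limit the centered kernel converges to the linear Gram matrix of the
  columns, so on row-centered data kPCA reproduces PCA and X ≈ A S
  holds to high precision; at finite σ the maps span a genuinely
  nonlinear feature space and X ≈ A S is only an approximation — this
  is inherent to kernel methods, not an implementation artifact.
* **ica** — maximum-likelihood ICA with a unit-scale Laplacian source
  prior (the scale is unidentifiable and is absorbed into A after
  whitening). Rows of X are whitened to C dimensions, then the square
  unmixing W is fit by natural-gradient ascent,
  W ← W + μ(I − sign(s)sᵀ/V)W, with step annealing: steps that lower
  the data log-likelihood are rejected and μ halved. Component order
  is fixed by descending map variance and signs by making each map's
  largest-magnitude voxel positive, so results are reproducible.
* **nsd** — non-stationary spatial source decomposition. Each source
  is modelled as Laplacian with a voxel-dependent scale λ(r)
  (piecewise constant over small regions). Under this model the local
  second moment over region r satisfies R(r) = A D(r) Aᵀ with D(r)
  diagonal, so A is identified by *joint diagonalization* of the
  region moments — second-order statistics only, no appeal to
  non-Gaussianity. Regions tile the mask into disjoint 4×4×4 boxes
  (trailing partial boxes kept, empty boxes dropped); moments are
  uncentered (⟨x xᵀ⟩), with per-region mean removal behind a flag.

  The fit minimizes Σ_r ‖R̂(r) − A D(r) Aᵀ‖²_F by alternating:
  (1) D-step — for each region, nonnegative least squares of vec R̂(r)
  on {vec(a_c a_cᵀ)} (source powers are variances, hence the sign
  constraint); (2) A-step — backtracking gradient descent
  (Armijo condition, adaptive step carry-over, up to 25 inner steps
  per sweep). After each sweep columns of A are renormalized to unit
  norm with the scale absorbed into D, which leaves the objective
  invariant. A is initialized from the top-C eigenvectors of the mean
  region moment. The objective trace is strictly non-increasing by
  construction (each half-step is a descent step); an increase raises
  an internal error. Stop at relative decrease < 1e−6 or 500 sweeps.

  Known statistical limitation: the least-squares objective weights
  all regions equally, so with few voxels per region (64 in a 4×4×4
  box) the minimizer partially fits Wishart sampling noise in R̂ and
  the recovered A carries irreducible finite-sample error even when
  the model is exactly right. On *noiseless* region moments recovery
  is exact (the test suite requires objective ≤ 1e−8 and column
  correlations ≥ 0.999). A stationary field (all D(r) equal) drives
  the objective to zero but leaves a rotation indeterminacy — the
  classical identifiability boundary, covered by a dedicated test.

Alignment utilities resolve permutation/sign/scale indeterminacies
for scoring: Hungarian assignment maximizing summed |correlation|, and
the Amari index of a gain matrix (normalized to [0, 1]; 0 iff a scaled
permutation). Separation quality of a fitted mixing Â against a true
A is always measured as amari(Â⁺A).

## Classification and statistics (classify_eval)

One fixed hyperparameter policy: SVM margin C = 1 everywhere; linear
kernels for sigmoid-bounded texture features and the combined feature
block, an RBF kernel for the (linear) time-course features, its γ
selected from {0.1·2^i | i = 0..10} by internal stratified 5-fold CV
with ties broken toward the smallest γ. Time-course features are
z-scored with training-set statistics by default; texture features are
not (they are already bounded in (0,1)); both are configurable.
Leave-one-out evaluation is cv_folds = n.

Statistics are exact where smallness matters: the baseline comparison
is a one-sided exact binomial tail on the correct count; McNemar tests
use the exact two-sided binomial on the discordant pair counts (p = 1
when there are none) — discordant counts between two classifiers on a
few hundred subjects are far too small for the χ² approximation.
Permutation tests shuffle labels (class counts preserved), re-split,
re-train and re-test per iteration (default 1000), reporting the
add-one p-value, which can never be exactly zero. Per-timepoint group
comparisons of a component's weights use Welch's t-test with no
multiplicity correction, reporting the count of time points with
case mean below control mean and the count with p ≤ 0.05; the raw
counts are the object of interest, so correction would change their
meaning.

Site audits address the multi-site confound: a linear SVM on one-hot
site indicators alone gives the accuracy ceiling a site-proxy
classifier could reach (its in-sample accuracy equals the per-site
majority rate), and site-balanced subsets downsample each site's
majority class so that a site-proxy classifier scores 50 %.

## Synthetic cohorts (synthetic)

The generators produce exactly the structure the method assumes, at
desk scale (defaults: 20×20×12 grid, T = 60, 20–60 subjects, noise
SD 0.1 — every stage runs in seconds): spatial sources Laplacian with
piecewise-constant scale fields on the same 4×4×4 tiling the NSD fit
uses (identifiability by construction; a mismatched tiling exercises
robustness), standard-normal subject time courses so the planted
group effect is in SD units, per-site additive offsets, Gaussian
observation noise, and structural volumes of smooth background plus a
group-dependent checkerboard texture. All generators are pure
functions of (spec, seed).

A dedicated construction, `simulate_variance_profile_mixture`, makes
sources that are separable *only* through second-order
non-stationarity: every source has the same marginal — half the
regions uniform (variance 1), half Gaussian (variance 1+√0.8 ≈ 1.894),
proportions chosen so the overall excess kurtosis is exactly zero —
with the region types placed independently per source. A stationary
4th-order method receives identically distributed, kurtosis-free
marginals and cannot identify the rotation; the regional variance
profiles remain fully informative. This is the fixture behind the
NSD-vs-ICA comparison.

What passing these tests shows — and does not. The synthetic data
match the model class exactly: no hemodynamics, no temporal
autocorrelation, no physiological noise spectra, no registration
error, and site effects that are simple additive offsets. Passing
demonstrates that the implementation inverts its own generative model
correctly, with the claimed statistical behaviour (power under a
planted effect, calibration under the null, confound detectability).
It does not certify accuracy on real clinical cohorts, where the
model assumptions hold at best approximately.

## Pipeline (pipeline, cli)

`run_pipeline` executes one mode (S, F, SF) end to end: fit everything
learnable on split = train (filters, reductions, maps, scalers, SVM
hyperparameters), evaluate exactly once on split = holdout, and write
report/manifest/predictions artifacts (the manifest records the config
hash and seeds). The CLI subcommands (`simulate`, `extract-structural`,
`extract-fmri`, `train`, `evaluate`, `permtest`, `site-audit`) are thin
wrappers over the same library functions, so synthetic and real
cohorts travel through the identical file-based path (NIfTI + TSV).

## Problem sizes used in the automated checks

Recovery checks run at K ≤ 6 mixture channels, C ≤ 5 sources,
V = 2 000–20 000 voxels, 10–12 regions or repetitions; the end-to-end
classification checks use n = 60 subjects on the default grid with
C_true = 4 and an effect of 1.5 SD (power) or 0 (null); the
permutation-calibration check uses 50 repeats of 99 iterations. These
sizes were chosen so the full suite documents the method's behaviour
in minutes while keeping every statistical margin wide.
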