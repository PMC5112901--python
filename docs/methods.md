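# Methods

## Reconstruction

The core quantity is the spin distribution function (SDF): per voxel, the
density of diffusing spins displaced along each unit direction û.  It is
computed directly on a standard-space grid: each standard voxel r is mapped
to the subject's native space by a diffeomorphism φ, the diffusion signals
are trilinearly interpolated at φ(r), sampling directions are transported
through the local Jacobian (û → J_φû/‖J_φû‖), and the summed density is
scaled by the Jacobian determinant so that compressed/expanded tissue keeps
its total spin count.  The kernel is the unnormalized sinc,
sinc(σ·√(6·D·bᵢ)·⟨ĝᵢ, û′⟩); a normalized sin(πx)/(πx) variant is available
behind `ReconConfig.sinc_normalized` since both conventions appear in the
q-space literature.

Parameters that matter:

- **σ (diffusion sampling ratio)** — dimensionless, default 1.25.  Scales
  the displacement range sampled by the SDF; lower values weight restricted
  diffusion more.
- **D (free-water diffusivity)** — mm²/s, default 2.51×10⁻³ (free water at
  body temperature).  Together with b it sets the sinc band limit
  L = σ√(6Db).
- **Z₀** — signal units.  Estimated per scan from the ventricle as the peak
  unnormalized SDF magnitude over ventricle voxels and sampling directions
  ("max" estimator: free water's peak density becomes exactly 1), or as the
  ventricle mean of per-voxel peaks ("mean").  Per-scan estimation makes
  the reconstruction invariant to the scanner's arbitrary signal scale.
- **Direction set** — a 321-axis antipodally reduced tessellated
  icosahedron (642 vertices) by default; any `DirectionSet` is accepted.

Numerical choices: signals at warped positions outside the subject FOV mark
the voxel as background (zeros) rather than extrapolating; negative sums
(possible because sinc oscillates) are clamped to zero and counted in the
log; the Jacobian of a displacement-field warp, when not supplied, is
computed by central finite differences along the world axes.  Warps with a
spatially constant Jacobian (identity, affine) take a fast path in which
the sinc kernel matrix is computed once for the whole volume; the general
path evaluates it per voxel and matches a per-voxel/per-direction/per-volume
reference loop to 1e-10 relative error (tested).

A practical note on rotational symmetry: for an isotropic voxel the finite
gradient scheme leaves residual angular ripple in the SDF of order 10⁻³ at
b = 2000 s/mm² with 64 directions.  The ripple comes from high-order
Legendre content of the sinc kernel sampled on finitely many directions —
it shrinks with the band limit, not with scheme density — so the exact
rotational-invariance check in the tests uses a symmetric icosphere scheme
at low b where the kernel is band-limited, and a per-mil tolerance covers
the clinical regime.

## Fingerprint

One entry per (voxel, fiber rank) of the direction atlas.  The SDF
magnitude at an atlas direction is the value at the nearest reconstruction
axis when the angular gap is ≤ 4°, otherwise an inverse-angular-distance
interpolation over the 3 nearest axes (angles treat directions as axes).
Entries are ordered lexicographically by voxel index — x slowest, then y,
then z, fiber rank innermost — on the canonical (ascending
left→right/posterior→anterior/inferior→superior) grid; volumes loaded from
NIfTI are reoriented to this canonical order first, so the serialization is
storage-independent.  The ordering convention is covered by the atlas
content hash stored in each fingerprint, making silently mismatched
fingerprints detectable.  Variance-1 scaling is applied globally to the
compiled vector (not per voxel), and subsetting a normalized fingerprint
(e.g. to a corpus-callosum mask) re-normalizes over the subset.

## Identification statistics

Distances are plain RMSE between equal-length vectors; the layer accepts
any feature vector (FA-style maps, flattened connectivity matrices) so
alternative modalities run through the identical analysis.  d′ uses sample
(n−1) variances.  The LOOCV classifier is a one-dimensional LDA with shared
pooled variance and class-frequency priors (equal priors behind a flag),
written in closed form and cross-checked against scikit-learn's LDA in the
tests.  GEV fitting is constrained maximum likelihood with the shape bound
k ≥ 10⁻⁶ (k > 0 keeps a finite lower support bound, respecting the
non-negativity of distances); the unconstrained scipy MLE initializes the
search.  The modeled classification error P(X_w > X_b) is computed as
∫₀¹ F_b(Q_w(u)) du by adaptive quadrature (absolute tolerance 1e-10) — a
bounded, smooth reformulation of the density integral — with a seeded
Monte-Carlo fallback.

## Similarity and group tests

Similarity = 100%·(1 − d₁/d₀) with d₀ the mean distance over
unrelated-subject pairs; when kinship labels exist, all same-family pairs
are excluded from the d₀ mean.  Mann-Kendall uses the exact null
distribution (inversion-count convolution) for tie-free series with
n ≤ 10 and the tie-corrected normal approximation with continuity
correction otherwise; its type-I error at α = 0.05 is verified by
simulation.  The drift rate is the OLS slope of similarity against days,
×100.  The Kruskal-Wallis omnibus is scipy's tie-corrected H; Scheffé's
simultaneous contrasts are applied to rank-transformed values by default so
the post-hoc family is coherent with the rank-based omnibus (a raw-value
ANOVA-residual variant sits behind `on_ranks=False`).  Permutation tests
use the add-one estimator p = (1 + #{T* ≥ T})/(1 + n_perm), default 10,000
permutations, seeded; the pairwise statistic is the one-sided difference in
group means.

## The phantom

`lcfp.phantom` emulates multi-subject, multi-session dMRI with a
stick-plus-ball signal model: per white-matter voxel, 1–3 fiber sticks with
volume fractions plus an isotropic compartment, a pure-free-water ventricle
block, and a single-shell 64-direction scheme at b = 2000 s/mm² with one
b0.  Density ("how much") varies across subjects through log-normal
multipliers on the fiber fractions while the stick diffusivity ("how
fast") is fixed — exactly the contrast that makes SDF magnitude a density
measure.  Defaults define the study conditions: 12×12×8 grid at 2 mm,
between-subject log-SD 0.15, drift 0, Rician noise.

- **Kinship** is a shared/unique decomposition of the subject effect,
  ε = √ρ·ε_family + √(1−ρ)·ε_unique, with ρ_MZ = 0.8 and
  ρ_DZ = ρ_sib = 0.4 by default — monozygotic twins share all of their
  genome, dizygotic twins and full siblings on average half, and the equal
  DZ/sibling coefficients reproduce the observed DZ ≈ sibling similarity.
- **Drift** multiplies all white-matter compartments by
  (1 − rate·days/100); the ventricle is untouched so per-scan Z₀
  normalization does not cancel the drift, and unnormalized fingerprint
  entries scale by exactly that factor through the full pipeline (tested to
  1e-6).  Because variance-1 normalization removes any uniform scaling, the
  *similarity*-trend recovery is exercised on synthetic similarity series
  with an imposed slope rather than through uniform density drift.
- **Noise**: Rician (magnitude MRI), SNR defined on the white-matter b0
  level.  The default SNR of 10 is calibrated so that repeat-scan
  similarity lands in the 70–80% band reported for real rescans — the
  regime where the method's central behavior (imperfect repeat similarity,
  yet error-free identification) must hold, and does.

What the phantom does **not** emulate: spatially correlated anatomy between
subjects beyond the shared template (real between-subject variance is
regionally structured), registration error (warps are exact), eddy-current
/ motion / susceptibility artifacts, multi-shell schemes, and partial-volume
gray matter.  Passing tests therefore demonstrate the correctness and
calibration of the machinery under the stated generative model, not
real-data effect sizes: phantom d′ (~60) exceeds real-data values (~7–15)
because real within-subject variance includes structured physiological
change the phantom's white noise does not capture, and phantom kinship
similarities (≈50/21/21% for MZ/DZ/sib at the default ρ) are likewise upper
bounds relative to the ~12.5/5.1/4.5% seen in vivo.

## Problem sizes

Test and acceptance runs use desk-scale designs chosen to keep the full
suite in the tens of seconds: 5×5×5 grids for oracle comparisons, the
12×12×8 default grid for cohort analyses, 10×2 scans for identification,
30 pairs per kinship group, 10⁴ draws for parameter-recovery checks, 10⁷
draws for the Monte-Carlo overlap oracle, and 10⁴ permutations where the
analysis defaults to that count.

## Known limitations

- The atlas "first resolved fiber" ranking is taken as given (descending
  base volume fraction in the phantom); real atlases may rank differently.
- The GEV shape bound occasionally binds for near-Gumbel data, in which
  case the fitted k sits at the boundary and the scale/location absorb the
  misfit.
- `estimate_z0`'s "mean" estimator averages per-voxel peaks; with strong
  ventricle partial voluming both estimators will underestimate the true
  free-water peak.
- Scheffé-on-ranks is a pragmatic pairing with the Kruskal-Wallis omnibus,
  not an exact simultaneous-inference procedure for ranks; the permutation
  tests are the assumption-free check.
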