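# Methods

## Model

`brainkrig` approximates Gaussian-process (kriging) prediction on the
sphere or plane with a finite multiresolution basis expansion.  For
observations y at locations x,

    y = X β + Φ(x) c + ε,   c ~ N(0, ρ Q_α⁻¹),   ε ~ N(0, σ² I).

* **Basis.**  Φ holds Wendland C⁴ kernels, w(r) = (1−r)⁶(35r²+18r+3)/3 on
  r ∈ [0, 1), centred on lattice nodes.  On the sphere, level ℓ nodes are
  the vertices of an icosphere of subdivision `base_subdivision + ℓ`
  (default levels: 42, 162, 642 nodes) and the kernel argument is the
  great-circle distance divided by the level's range (range_multiplier ×
  the median nearest-node arc; default multiplier 2.5).  On the plane,
  nodes form square grids whose spacing halves per level, padded one
  spacing beyond the image, with Euclidean distances.  The compact support
  keeps Φ sparse.
* **Coefficient prior.**  Per level, a spatial-autoregressive precision
  Q = BᵀB with B = diag(degree + κ²) − A over the lattice neighbor graph
  (icosphere edges / 4-neighbor grid).  κ² defaults to 0.01 — just enough
  to make the prior proper; it is exposed in every config.  Levels are
  weighted by α (default (1, 0.25, 0.01), i.e. most process variance at the
  coarsest scale): the joint penalty is block-diagonal with blocks Q_ℓ/α_ℓ.
* **Fit.**  With λ = σ²/ρ, β and c jointly solve the penalized normal
  equations of min ‖y − Xβ − Φc‖² + λ cᵀQ_α c.  The fixed part defaults to
  an intercept (a linear trend is config-gated).  λ is either fixed or
  grid-selected by GCV (default) or profile likelihood; ties break toward
  the larger λ, preferring the more conservative fit.  An optional basis
  normalization divides each design row by the prior-implied marginal
  process standard deviation; it is off by default so the algebra stays a
  transparent penalized least squares.

Distances are radians on the unit sphere throughout.  A millimetre reading
requires an explicit sphere radius; none is assumed.  The minimum-distance
evaluation restriction defaults to 0.1 rad on the sphere and 25 px on the
plane.

## Analysis stages

* **Extreme-tail prediction** (`threshold_mask` + `krige_from_mask`): the
  mask is the bottom (or top) quantile of valid vertices, count
  round(q·V), boundary ties resolved by ascending vertex index; invalid
  (medial-wall) vertices never enter masks, fits, or metrics.  Only masked
  locations/values reach the fit; out-of-mask observations are used purely
  for evaluation (a permutation test of this no-leakage property is in the
  suite).  Agreement is Spearman's ρ with average-rank ties, reported for
  all out-of-mask vertices, for observed-positive vertices, and beyond the
  minimum distance; sets with fewer than 10 vertices yield a flagged
  undefined metric rather than an error.
* **Task specificity** (`pairwise_specificity`): both fits use the
  conjunction of the two tasks' bottom-quantile masks (guard: ≥ 50
  vertices); predictions from task A's and task B's values are both scored
  against A's observed values over the complement of A's mask.  All three
  restrictions are post-hoc filters of the same two fits.  A tie is
  declared only below 1e-12 — the identical-map case.
* **Network analysis** (`network_prediction`): raw (unthresholded) values
  inside each labeled network predict the complement; networks under 50
  vertices are flagged and skipped.
* **Spin null** (`spin_null`): Haar-random proper rotations (QR with
  sign-corrected diagonal), label transport by nearest-vertex lookup under
  the inverse rotation, add-one p-values (1 + #{null ≥ obs})/(n + 1), and
  both Benjamini–Hochberg and Bonferroni corrections reported side by
  side.  Rotations that lose a required label on the valid surface are
  resampled and logged.  When λ is fixed, the per-rotation refit reuses a
  precomputed dense design; this path is verified to machine precision
  against the estimator path.
* **Eigenmode surrogates** (`eigenstrap`): the map's coefficients in the
  Laplace–Beltrami eigenbasis are rotated by independent Haar-orthogonal
  matrices within eigengroups, reconstructed, and optionally rank-remapped
  onto the original value multiset (exact histogram preservation).
  Eigengroups follow the eigenvalue clustering (relative tolerance 1e-3)
  only when it recovers the spherical-harmonic shell sizes 3, 5, 7, …;
  otherwise fixed 2ℓ+1 blocks are used.  On icosphere spectra the
  icosahedral symmetry splits shells by ~1% — far more than any safe merge
  tolerance — and because modes are sorted by eigenvalue the fixed blocks
  still align with the true shells, whereas shell-straddling groups would
  leak power across spatial scales and bias surrogates rough.
* **Planar variant** (`frame_predict`/`series_analyze`): per-frame
  top-quantile masks over valid pixels, an independent model per frame,
  Euclidean (config: Chebyshev) pixel distance to the mask, and
  across-frame inference on Fisher-z correlations via a one-sided
  one-sample t-test and an AR(1)-adjusted test — an autoregression with
  intercept fitted to the z series, testing the process mean c/(1−φ) with
  a delta-method standard error.  The AR order is exposed; order 1 is the
  default because the frame series is short and a single autocorrelation
  parameter already dominates the correction.  No temporal smoothing or
  detrending is applied.

## Eigenmodes

The default discrete Laplacian is the cotangent Laplace–Beltrami operator
with barycentric lumped vertex-area mass, restricted to valid vertices (an
unweighted graph Laplacian is available).  Modes are M-orthonormal,
ascending, with a constant first mode at eigenvalue 0; signs are fixed by
making each mode's largest-magnitude entry positive.  A disconnected valid
submesh is an error naming the component sizes.

## Synthetic data

Generators are pure functions of (spec, seed) and define the conditions
under which the package's claims are tested:

* `synth_map`: Σ_k a_k λ_k^{−γ/2} ψ_k + ε on the mesh eigenbasis
  (constant mode excluded), standardized over valid vertices.  γ controls
  smoothness analytically — the generator's autocorrelation is exactly the
  truncated power-law spectrum, matching the surrogate machinery.  γ ≥ 3
  gives strongly autocorrelated z-map-like fields; γ = 0 a flat band-limited
  spectrum; `n_modes=0` with `noise_sd>0` pure white noise (γ < 0 is
  rejected).  Default noise_sd 0.05 adds a small nugget, as in real
  contrast maps.
* `synth_task_family`: task_i = √w·S + √(1−w)·U_i with independent draws;
  expected pairwise correlation w (default 0.5, a realistic cross-task
  similarity for task-contrast families).
* `synth_networks`: balanced multi-source region growing on the mesh graph
  (always extending the currently smallest network), giving n labeled
  networks of comparable area; `patches_per_network` controls distributed
  vs compact geometry.
* `synth_movie`: planar Gaussian random fields with isotropic |k|^{−γ}
  Fourier spectrum, AR(1) in time (stationary lag-1 correlation φ,
  default 0.8), inside an elliptical validity window covering ~64% of the
  frame.

What these emulate: smooth antagonistic z-maps, shared-plus-unique task
structure, a 7-network-style parcellation, and temporally autocorrelated
imaging frames.  What they do not: hemodynamics, indirect vascular
coupling, nonstationary (regionally varying) autocorrelation, subject
variability, or measurement artifacts.  Passing tests therefore establish
the geometric/statistical mechanism — extreme-tail prediction rides on
spatial autocorrelation — not fidelity to any specific acquisition.

## Numerical choices and degenerate inputs

* Normal equations are solved via a dense Cholesky of the (small)
  node-count system; singular systems at λ = 0 raise advice to use λ > 0,
  and non-positive-definite cases fall back to least squares.
* Spearman metrics treat numerically constant inputs (relative spread
  ≤ 1e-10) as undefined rather than propagating solver round-off.
* |ρ| = 1 entries are clipped to ±(1 − 1e-12) before Fisher transform,
  with a warning.
* Points outside every basis support predict as the fixed part only, with
  a warning.
* Quantile-boundary ties, eigenmode signs, and λ-grid ties all have
  deterministic resolutions, so identical configs reproduce outputs byte
  for byte.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run on icosphere meshes of
642–2562 vertices, lattices of 42–846 nodes, 200-mode eigenbases, 200
surrogates, 200-run × 200-rotation spin calibrations, and 40-frame 48×48
movies.  These sizes were chosen so the complete verification runs on a
laptop-class single core in minutes while every statistical property
(calibration intervals, majority-vote wins, oracle tolerances) is still
sharply testable; all of them scale up by configuration only.

## Known limitations

* Covariance is spatially homogeneous; nonstationary or folded-surface
  (mid-thickness) geodesic variants are out of scope.
* Node counts follow plain icosphere subdivision; other near-equidistant
  sphere grids would give slightly different counts at the same scale.
* Spin transport by nearest-vertex lookup is not exactly bijective on an
  irregular mesh; label counts are preserved only to ~2%.
* The AR adjustment models the z-series mean, not frame-level spatial
  error correlation.
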