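# Methods

This note documents the models, numerical choices and limitations of
`slicocc`. Everything quantitative below is computed by the test suite or
`scripts/acceptance.py`; nothing is quoted from elsewhere.

## Occupancy model and phantom

Voxel occupancy follows the hyperbolic Emax law Occ = Occ_max·C/(C+EC50),
with C the plasma concentration in ng/mL. The digital phantom assigns a
ground-truth EC50 volume on a 64×64×64 grid (1 mm isotropic): an
ellipsoidal brain of ~1.09×10⁵ voxels, two bilateral "caudate-like"
ellipsoids (1,637 voxels each) at EC50 = 25 ng/mL, two bilateral
"putamen-like" ellipsoids (1,569 voxels each) at EC50 = 50 ng/mL, and a
background drawn per voxel from U[6, 10] ng/mL. Occ_max is 0.85
everywhere. The geometry is analytic (ellipsoids) rather than atlas-based,
which makes it license-free and exactly specifiable; hot-spot masks are
validated to lie inside the brain and not overlap.

Defaults and why:

- **Concentrations** — 10 log-spaced values from 3 to 279 ng/mL
  (`np.geomspace(3, 279, 10)`). Log spacing covers the dynamic range of the
  saturation curve from well below the background EC50 to several times the
  hot-spot EC50.
- **Noise** — after generating the ideal series, each in-mask voxel at each
  concentration receives independent Gaussian noise with SD
  σ = −0.22·Occ + 0.25 (occupancy-dependent: noisier at low occupancy).
  Values are deliberately *not* clipped to [0, 1]; clipping would skew the
  noise distribution and bias the fits. A spec whose (slope, intercept)
  makes σ nonpositive anywhere on [0, Occ_max] is rejected.
- **Smoothing** — each noisy volume is convolved with a normalized 3×3×3
  Gaussian kernel with σ = 0.5 voxels, to give the series the spatial
  correlation of real occupancy images. The kernel size is fixed at 3³
  rather than derived from σ. Outside-mask voxels are zero-filled before
  convolution and the mask re-applied afterwards; there is no boundary
  renormalization (boundary voxels are a small fraction of the mask and
  the voxel-level noise statistics are dominated by the interior).
- **Seeding** — a single study seed feeds stage-specific RNG streams
  (background draw, noise, voxel subsampling) derived by hashing the stage
  name into a `SeedSequence`, so stages are individually reproducible from
  one knob and all derived seeds stay below 2³¹.

What the generator does *not* emulate: anatomy (the regions are
ellipsoids), scanner resolution/point-spread beyond the single smoothing
kernel, within- and between-subject variability of human occupancy data,
and any upstream kinetic modeling that produces occupancy images from raw
PET. Passing tests therefore demonstrate the statistical behavior of the
method under the stated noise model, not performance on human data.

## SLIC-Occ clustering

A localized k-means over the V-channel occupancy curves. Per voxel the
distance D = sqrt(d_feature² + (d_spatial/S)²·m²) is minimized, with
S = ∛(N/K) for N in-mask voxels and K requested clusters; each iteration
scans a 2S×2S×2S window centered on every cluster's current (moving)
center, assigns each in-mask voxel to its argmin-D center, then updates
centers to member means of position and curve. Iteration stops at
`max_iter` (default 10) or when the mean center displacement falls below
`tol` (default 0.1 voxels) — standard SLIC practice. Empty clusters are
dropped and labels compacted at the end; masked voxels reached by no
window (possible with irregular masks) are assigned by global argmin of D.

Numerical/design choices:

- **Seeding** is a plain regular grid with spacing exactly S, centered on
  the mask's bounding box. Seeds keep fractional positions; a seed is kept
  when the trilinearly interpolated mask fraction at its position exceeds
  1/2, and its initial curve is the trilinear interpolation of the series.
  Fractional symmetric positions (rather than snapping to voxels) make the
  seeding exactly equivariant under grid flips and axis permutations, so
  the final partition is orientation-invariant — verified by test. With
  density 1/S³ the expected cluster volume is N/K.
- **Tie-breaking**: equal-D candidates resolve to the lower center index
  (centers enumerated in lexicographic grid order), making runs
  bit-reproducible.
- **Feature scaling**: occupancy channels enter the feature distance raw —
  occupancy is already dimensionless and bounded — and only the spatial
  term is normalized by S.
- **Connectivity** is not enforced by default (clusters may be spatially
  disconnected if their curves agree); an optional flag reassigns minor
  fragments to the dominant neighboring cluster.
- m controls the precision/accuracy trade-off: small m chases occupancy
  boundaries (accurate but noisy clusters), large m tends to the spatial
  Voronoi partition of the seeds (regular clusters, larger boundary
  mixing). m = 0.5 with ~265-voxel clusters is the default operating
  point; the sweep utility tabulates CV and bias over any (m, K) grid.

## Emax fitting, model selection, precision

Per curve (a voxel's, or a cluster's mean curve) two fits are computed:
EC50-only with Occ_max fixed (1-parameter) and joint (Occ_max, EC50)
(2-parameter). The fixed Occ_max defaults to 1.0 — the conventional
full-occupancy assumption — and is configurable. Bounds: Occ_max ∈
(10⁻³, 1], EC50 ∈ (10⁻³, 10·max(C)); an EC50 far beyond the sampled
concentrations is not identifiable. Initialization is deterministic: a
20-point log-spaced EC50 grid scan with the amplitude profiled out in
closed form (for fixed EC50 the optimal amplitude is linear least
squares), then bounded trust-region refinement with the analytic Jacobian
(∂Occ/∂Occ_max = C/(C+EC50), ∂Occ/∂EC50 = −Occ_max·C/(C+EC50)²).

Model choice is by AICc (lower wins; ties go to the 1-parameter model; an
unconverged candidate loses). SSE is floored at 10⁻¹² inside the AICc
logarithm so noiseless curves do not produce −∞. Non-finite curve points
are dropped with n adjusted; curves with fewer than 3 finite points are
flagged failed and excluded downstream. σ_fit is the square root of
diag((JᵀJ)⁻¹·RᵀR/(n−p)) at the solution; a rank-deficient Jacobian yields
NaN (flagged) rather than a spurious value. CV(EC50) = σ_fit(EC50)/EC50.

Negative occupancy values (possible under the unclipped noise model) are
retained in fitting — least squares handles them and discarding them
would bias the estimates.

## Evaluation

Region summaries report the voxelwise mean ± SD of the EC50 and CV maps
over ground-truth regions; failed-fit voxels are excluded and counted.
Accuracy is the signed percent bias of the *region-mean* estimate against
the region-mean truth (regions selected from the truth labels), and the
precision gain of clustering is the ratio of region-mean voxel-level CV to
region-mean cluster-level CV, also expressed as a percent reduction
100·(1−1/ratio) — so both fold-style and percent-style statements can be
checked directly. The sweep runs the cluster-level pipeline over an (m, K)
grid and tabulates CV and bias per region; failed combinations are
recorded, not fatal.

## Problem sizes

The shipped defaults are the desk-scale study: 64³ grid, ~1.09×10⁵ in-mask
voxels, K chosen to preserve the ~265-voxel cluster volume of a full-scale
(121×145×121, K = 8000) analysis, i.e. K ≈ 412. Cluster-level fitting
covers the whole mask (~440 clusters, seconds); voxel-level fitting in the
acceptance run is restricted to the hot spots plus a 10⁴-voxel background
sample, which preserves the regional statistics while keeping the run to a
couple of minutes. The noise-model check uses 18 occupancy levels with
13,824 draws each.

## Known limitations

- Cluster-level EC50 is biased low near hot-spot boundaries (mixed curves
  fit an intermediate EC50); the bias grows with m and shrinks with K, as
  the sweep shows. Region-mean bias on the default phantom is in the
  −5…−15% range at the default operating point.
- The CV from the least-squares covariance is a local, asymptotic measure;
  for strongly heterogeneous clusters it reflects lack-of-fit as well as
  noise.
- Smoothing across the mask boundary uses zero-padding, slightly deflating
  occupancy in the outermost voxel shell.
- The 2S search window means very elongated masks can leave voxels
  unreached by any window; the global-fallback assignment preserves the
  partition but those voxels are effectively unwindowed k-means.
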