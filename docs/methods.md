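# Methods

## Coordinate and data conventions

All geometry is computed in physical micrometers. A `Volume` stores its grid
depth-slowest (`voxels[k, j, i]`, TIFF stack-page order) with spacing
`(sx, sy, sz)`; voxel index `(i, j, k)` sits at
`origin + (i·sx, j·sy, k·sz)` (voxel centers, 0-based). Transforms never act
on indices — the two modalities have different and partly anisotropic
spacings (IVM lateral ≪ axial; microCT isotropic ~0.75 µm). Frames are
tagged `ivm`/`microct` and checked when points are mapped.

## Registration ladder

Given paired landmarks (vessel bifurcations and similar features marked in
both volumes, typically 10–20 pairs), four nested models are available:

- **rigid** — Procrustes/Umeyama closed form: SVD of the cross-covariance,
  with the sign of the smallest singular direction flipped if needed so the
  rotation is proper (det = +1) even for reflective noise configurations.
- **similarity** — same, with the optimal isotropic scale. This is the
  workhorse coarse model: chemical fixation and resin embedding shrink
  tissue roughly isotropically, so a scale is the minimum physics the
  registration must carry.
- **affine** — 12-parameter least squares via the pseudoinverse; absorbs
  anisotropic shrinkage and shear.
- **TPS** — 3D thin-plate spline with kernel φ(r) = r (the biharmonic
  Green's function in 3D; r² log r is the 2D kernel and would be wrong
  here). The bordered system enforces the side conditions Σw = 0,
  Σw pᵀ = 0; regularization λ (µm-scaled, added to the kernel diagonal)
  interpolates exactly at λ = 0 and tends to the affine fit as λ → ∞.

Degenerate configurations (too few points, collinear/coplanar sources,
design-matrix condition number > 1e8, duplicate TPS controls) are rejected
with explicit errors rather than returning unstable fits.

The default pipeline is two-stage: similarity on the full landmark set, then
TPS (λ = 0.01) on the residual correspondence, mirroring a coarse overview
registration refined with higher-magnification acquisitions. Error
reporting: FRE (RMS at the landmarks) and LOO-TRE (each pair held out, both
stages refit, error at the held-out pair; RMS). FRE flatters the fit —
LOO-TRE is the number to trust as an estimate of error at the target.

**When the fine stage helps.** TPS at small λ interpolates whatever the
landmarks contain, deformation and localization noise alike. On phantoms
where the nonlinear deformation clearly exceeds the landmark noise
(e.g. ≤6 µm warp, 0.3 µm noise) the two-stage pipeline beats the similarity
alone; at noise comparable to the warp (1 µm vs a mean 1.5 µm displacement)
the similarity alone is often slightly better at the target, because
averaging over 15 pairs suppresses noise that the spline would reproduce.
Both configurations stay well inside the 5 µm budget; the LOO-TRE in the
registration report is the practical guide for choosing.

TPS inversion (needed to carry microCT annotations back to the IVM frame)
is a per-point fixed-point iteration x ← x − (T(x) − y) started from the
affine-part inverse, tolerance 1e-4 µm, 100 iterations — ample for the
few-µm deformations of embedding distortion.

## Target prediction

Block faces are planes fit by total least squares (centroid + smallest
principal direction) to operator-segmented patches of the microCT block
surface, oriented outward against a user-supplied interior point. The front
face and flank of a trimmed block are near-perpendicular; a |cos| > 0.05
between their normals warns, > 0.3 is an error. The prediction maps the IVM
target through the fitted transform and reports magnitudes of the signed
point–plane distances (negative = inside). The TRE estimate attached to a
prediction is the registration's LOO-TRE.

## Trim planning and checkpoint correction

Model: the microtome removes `nominal × k × (1 + ε)` per feed, with a
constant per-session scale error k (|k − 1| up to ~0.10 — the dominant term,
consistent with feed inaccuracy being systematic relative to the nominal
setting) and small per-cut noise ε. The split between systematic and random
components is a modeling choice; both are configurable.

Checkpoints are scheduled geometrically in the remaining distance: with n
checkpoints to a stop depth S (target minus a final offset, default 4 µm so
the face stops just short of the cell), each leaves a fraction
ρ = (5 / (0.10 · S))^(1/n) (capped at 0.7) of the previous remainder, so the
final uncorrected segment times the worst-case 10% error stays ≤ 5 µm. For
S ≈ 500 µm and n = 4 the checkpoints fall at ~216, 338, 407, 446 µm. At
each checkpoint a 0.5 µm section is matched against oblique virtual microCT
slices parallel to the block face (both images brought to a common pixel
size, blurred σ = 2 px to absorb stain/modality contrast, compared by
zero-normalized cross-correlation; argmax over depth, ties to the shallowest
candidate because overshoot destroys the sample). The scale estimate is the
regression through the origin k̂ = Σ d·f / Σ f² over all observations, and
the remaining nominal feed is rescaled by 1/k̂. With one noiseless
checkpoint this identifies a constant k exactly; k̂ outside [0.8, 1.2]
indicates a mismatched checkpoint and is an error. Flank trimming reuses the
same machinery against the flank plane with its own margin (~20 µm).

## Phantom generator

The phantom emulates the study conditions end to end: a branching vessel
network grown by seeded random walk (5 µm steps, direction jitter, branching
probability 0.16/step into two children at 0.8× radius from 4 µm roots),
steered back inward within 10 µm of the volume walls so the network stays in
the imaged tissue, and terminated below a 1.5 µm radius floor — capillary
scale, and the thinnest tube the rendered grids (IVM axial spacing 2 µm)
meaningfully resolve. The floor and steering keep the generator's total
length stable across seeds (±~25% of the median) and its tubes segmentable;
sub-resolution vessels would add ground truth that no pipeline stage could
recover.

Renderings: IVM as blurred (σ 1 µm) tube rasterization with exp(−z/τ) depth
attenuation (τ default 80 µm) and 2% Gaussian noise, lateral/axial spacing
(0.5, 0.5, 2) µm — an assumed two-photon sampling, not a measured value —
plus a separate cell channel (10×8×8 µm ellipsoid at the target, which sits
adjacent to a bifurcation, where arrested cells lodge). MicroCT at 0.75 µm
isotropic with inverted contrast (resin bright, tissue intermediate, vessels
darkest) inside a block with planar, ≤3° tilted front/flank faces recorded
as ground truth. The ground-truth deformation is a similarity (scale
U(0.85, 0.95), rotation ≤ 10°, translation U(±10) µm) composed with a TPS on
a 3³ control grid whose displacements are random directions with magnitude
U(0, 3 µm) — drawn as direction × magnitude so the mean displacement is
exactly half the configured maximum. Landmarks are a uniform random sample
of 15 bifurcations with independent N(0, 1 µm) localization noise on both
sides. Everything is reproducible bit-for-bit per seed.

What the phantom does *not* model: point-spread anisotropy and scattering,
vessel diameter variation along a segment, staining texture inside tissue,
section compression and knife marks, or laser-branded fiducials. Passing the
recovery bounds here shows the computation is correct and that the error
budget (landmark noise + residual deformation + feed error) closes at <5 µm
under realistic magnitudes — not that any particular instrument will achieve
those magnitudes.

## Numerical and design notes

- Depth-intensity normalization defines foreground per slice by a quantile
  (default 0.75) and linearly rescales each slice so foreground mean/SD
  match the global foreground statistics. The quantile-defined foreground is
  invariant under the per-slice affine map, making the operation idempotent;
  slices with an empty foreground pass through unchanged with a warning.
  The equalization is exact when slices share a texture modulated by a
  depth-only gain; for sparse structures the quantile must roughly match the
  true foreground fraction, and global-threshold segmentation of the raw
  volume is often the more robust route.
- Oblique slices use pixel-center sampling, trilinear interpolation, fill 0
  outside the volume with an out-of-volume sample count on the result
  (block faces legitimately sit at the volume edge).
- Resampling preserves the physical extent to within one voxel and is the
  identity at the original spacing; degenerate single-voxel axes use
  nearest values.
- Segmentation: 26-connectivity for components, 6-connectivity for surface
  voxels; Otsu/quantile thresholds make the mask invariant to global
  intensity scaling. Interactive region-growing ("magic wand") workflows are
  approximated by quantile thresholds; hand-corrected masks can be supplied
  as files.
- Monte-Carlo sizes (200 phantom registrations, 500 trim simulations, 50–100
  seeds for distributional test properties) were chosen as the sizes at
  which the compared statistics stabilize; all are seeded.
- NRRD I/O goes through SimpleITK (spacing and origin in the header); TIFF
  carries spacing in a YAML sidecar. Integer volumes round-trip bit-exactly.

## Known limitations

- No intensity-based (e.g. mutual-information) registration and no automatic
  landmark correspondence search: pairing is operator-supplied, as in the
  interactive workflow this replaces.
- Checkpoint matching assumes the physical section is parallel to the block
  face and un-deformed; compression or folding of real thick sections will
  bias the depth estimate by up to the section tilt times the field size.
- The TPS numeric inverse is only guaranteed for deformations small enough
  that the fixed-point map contracts (gradient of the nonlinear part < 1),
  which holds for embedding-scale warps but not for arbitrary splines.
- Plane-based block faces ignore face curvature from imperfect trimming.
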