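# clemtarget

Micrometer-accurate retrieval of a single cell for correlative light–electron
microscopy (CLEM), computed rather than hunted.

## The problem

Intravital microscopy (IVM) can watch a single fluorescent cell — say, a tumor
cell arrested in a brain capillary — but cannot resolve its ultrastructure.
Volume electron microscopy can, but only after the tissue is fixed, stained
with heavy metals, and embedded in a resin block, which quenches the
fluorescence and shrinks and warps the sample. Finding one 10 µm cell inside a
millimeter-scale opaque block by serial sectioning can take months.

`clemtarget` implements the computational core of a microCT-bridged workflow:
the resin-embedded block is imaged by X-ray microtomography (microCT,
~0.75 µm isotropic), in which the vessel network is visible (vessels are
*less* dense than the stained tissue). The same network was recorded by IVM,
so corresponding vessel landmarks registered across the two volumes carry the
target's IVM coordinates into the block's frame — without ever seeing the
cell in microCT. The package is for microscopists and image analysts running
or simulating such targeting experiments.

## What it computes

- **Landmark registration** (`clemtarget.registration`). From N paired points
  x_i (IVM) and y_i (microCT), closed-form least-squares fits of the nested
  transform ladder: rigid (Procrustes/Umeyama SVD with proper-rotation
  correction), similarity (adds isotropic scale c — embedding shrinks tissue
  by 5–15%), general affine, and a 3D thin-plate spline
  T(x) = A x + t + Σᵢ wᵢ φ(‖x − pᵢ‖) with the 3D biharmonic kernel φ(r) = r,
  solved from the standard bordered system with ridge λ on the kernel
  diagonal. Two-stage (coarse → fine) composition, fiducial registration
  error (FRE), and leave-one-out target registration error (LOO-TRE).
- **Target prediction** (`clemtarget.targeting`). Block faces are
  total-least-squares planes fit to face point clouds; the prediction reports
  the mapped position and its distances to the front face and flank — the
  numbers the ultramicrotome operator trims against.
- **Trim planning and checkpoint correction** (`clemtarget.trimming`). The
  microtome's nominal feed errs by a ~constant 5–10% scale. A geometric
  checkpoint schedule (each checkpoint leaves a fraction ρ of the remaining
  distance, ρⁿ · depth · 0.10 ≤ 5 µm) plus zero-normalized cross-correlation
  matching of 0.5 µm check sections against oblique virtual microCT slices
  re-estimates the scale k̂ = Σ d·f / Σ f² en route, so the final face stops
  within 5 µm of the target.
- **Volumes and segmentation** (`clemtarget.volumes`, `.segmentation`).
  TIFF/NRRD volume I/O with physical spacing, depth-gradient intensity
  normalization, trilinear resampling, oblique virtual sections, and
  threshold-based vessel segmentation with surface point extraction.
- **Phantoms** (`clemtarget.phantom`). Synthetic branching vessel trees
  rendered in both modalities under a known similarity + TPS deformation,
  with ground-truth target, landmarks, and block geometry — every stage is
  testable without any acquisition.

## Worked example

Run the full synthetic pipeline — generate phantoms, register, predict the
target, and simulate checkpoint-corrected trimming:

```sh
$ clemtarget simulate --seed 7 --n-cases 20 --n-trim-runs 100
{
  "n_cases": 20,
  "target_error_um": {"median": 1.86, "p95": 3.10, "max": 3.18},
  "n_trim_runs": 100,
  "trim_error_um": {"median": 0.41, "p95": 1.11},
  ...
}
```

The target is predicted inside the block to 1.9 µm (median) across phantoms
with 0.85–0.95 shrinkage, ≤10° rotation, ≤3 µm nonlinear warp, and 1 µm
landmark noise; the simulated 500 µm trim approach stops within ~0.4 µm of
its planned depth. Plan a real approach from a predicted depth:

```sh
$ clemtarget trimplan --target-depth 415 --n-checkpoints 4 --out plan.json
target depth 415.0 µm, stop at 411.0 µm
  checkpoint 1: depth    168.3 µm  (feed   168.3 µm)
  checkpoint 2: depth    267.6 µm  (feed    99.4 µm)
  checkpoint 3: depth    326.3 µm  (feed    58.7 µm)
  checkpoint 4: depth    361.0 µm  (feed    34.7 µm)
  final segment: feed    50.0 µm
```

Each checkpoint leaves ~59% of the remaining distance, so even an
uncorrected 10% feed error over the final 50 µm stays within 5 µm. The other
subcommands (`segment`, `register`, `predict`, `checkpoint`) cover the
individual stages on files; see `clemtarget <cmd> --help`.

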