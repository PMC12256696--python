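# Methods

This note documents the models, numerical choices, and validation logic behind
`latticeplan`. The package implements the computational stages of a
simulation-free lattice-radiotherapy (LRT) workflow and validates every stage
on seeded digital phantoms; nothing here depends on patient data.

## Coordinate and raster conventions

Volumes are `(x, y, z)` arrays with `z` the axial slice index; physical
coordinates are millimetres in patient LPS. The `origin` is the position of
the *center* of voxel `(0,0,0)`, so voxel `(i,j,k)` sits at
`origin + (i,j,k)·spacing`. Displacement fields are stored in mm on the
fixed-image grid (mm rather than voxels, so fields are meaningful across
resolutions); a zero field makes the warp the identity, exactly. All
out-of-bounds image samples take −1024 HU (air), matching the background value
the preprocessing stage writes. Dose is carried in cGy throughout.
`resample_to_shape` preserves the physical field of view (outer voxel edges
fixed, spacing rescaled); intensity images are interpolated trilinearly, masks
nearest-neighbor so they stay binary. NIfTI I/O restricts affines to
axis-aligned scaling + translation; a JSON sidecar format is accepted for
small array fixtures.

## Digital phantoms

`make_phantom` builds paired diagnostic/planning CTs of the same "patient":

* **Anatomy**: an elliptic-cylinder torso (soft tissue 40 HU) optionally
  capped in z by rounded superellipsoid ends; two ellipsoidal lungs (−700 HU);
  a posterior spine column of vertebral bodies (bone 700 HU, marrow core) with
  a 37 mm repeat and 13 mm disc gaps — the period is deliberately
  incommensurate with common slice spacings so that rigid alignment along z is
  well-posed; a sternum bar; an optional gastric gas pocket (abdomen).
* **Couches**: the dCT carries a curved shell couch, the pCT a flat slab
  (both 200 HU, 12 mm thick, separated from the skin); couch geometry is the
  main systematic difference between the two acquisitions.
* **Deformation**: the ground-truth field mapping dCT anatomy onto the pCT is
  the sum of a *systematic couch-induced sag* (a +y displacement strongest
  anteriorly, tapering posteriorly and laterally — moving from a curved to a
  flat couch flattens the patient's back) and a *seeded random residual*
  (per-component white noise, Gaussian-filtered at 40 mm, rescaled to a stated
  maximum amplitude). Defaults are 3 mm sag + 3 mm residual; model-validation
  phantoms use 4 mm + 1 mm so the learnable systematic component dominates.
* **Partial volume**: HU images are rendered with a 2×2×2 sub-voxel quadrature
  (samples at ±spacing/4). Point-sampling the hard-edged analytic scene would
  make sub-voxel shifts invisible — boundary voxels would not change until a
  sample crossed an edge — which breaks sub-voxel registration recovery.
  The pCT is rendered by evaluating the anatomy at displaced sample points,
  so its deformation is exact (no resampling error); masks are rasterized the
  same way and are exact.
* **Noise**: additive Gaussian HU noise, default σ = 10 HU, independent
  between the two scans.

Everything is bit-reproducible under a fixed seed. What these phantoms do
*not* emulate: realistic organ shapes and textures, scanner-kernel spectra,
respiratory motion, truncation, arm-position changes, and bowel/gas motility
beyond a static gas pocket. Passing tests therefore demonstrate correctness
of the *machinery* (geometry, optimization, bookkeeping) and qualitative
behavior of the learning stage, not clinical-grade synthetic-CT accuracy.

## Preprocessing

Couch removal thresholds each axial slice at −200 HU, keeps the largest
8-connected 2D region (the patient cross-section is larger than the couch
shell), then applies a 3D morphological closing (ball radius 3 voxels; the
array is edge-padded first so anatomy touching the grid faces is not eroded by
the implicit zero border) and a 3D dilation (ball radius 2) for skin
continuity. Everything outside the final mask becomes exactly −1024 HU.
Slices with no above-threshold voxel are allowed (beyond the anatomy); a
volume with none anywhere is an error. The operation is idempotent.

Rigid registration maximizes NCC between *bone-emphasized* feature maps: a
soft threshold (linear ramp over 300 HU centered on the 300 HU bone threshold)
followed by a Gaussian blur specified in mm (default 6 mm). Two numerical
points matter:

* a *soft* threshold is used instead of hard binarization because binarization
  quantizes boundary positions to the voxel grid and empirically caps recovery
  accuracy at about half the slice thickness — far worse than the 0.5 mm
  target;
* the fixed feature map is pre-shifted by half a voxel (the shift is folded
  back out of the returned transform) so that both sides of the NCC carry one
  trilinear-interpolation pass. Without this, integer-voxel candidate offsets
  enjoy an artificial sharpness bonus — a spurious NCC spike at zero shift
  that traps the optimizer (rotations about z never interpolate in z at all).

Optimization is Powell from the identity with 0.01 mm/deg parameter tolerance.
On noise-free phantoms a (5, −3, 2) mm / 3° motion is recovered within
0.4 mm / 0.2° at 4 mm resolution. `preprocess_pair` chains: couch removal →
registration + resampling of the dCT → resampling of both to 128×128×64
(FOV preserved), with a per-stage MAE log.

## Deformation-field model

A 3D convolutional encoder–decoder (numpy, manual backpropagation) maps the
normalized dCT to a dense DVF; the synthetic CT is the warped dCT, so every
sCT voxel is a trilinear combination of dCT voxels — the model cannot
hallucinate intensities. Architecture: initial 2× average-pool; per level a
3×3×3 convolution + leaky ReLU then 2× pooling; a bottom block; a mirrored
decoder with nearest-neighbor upsampling and skip concatenation; a 1×1×1
zero-initialized head producing the field at half resolution, upsampled to
full resolution by a separable linear upsampler with an exact adjoint.
Zero-initialization makes the untrained model the exact identity warp.
Defaults: 3 levels, 32 start channels; toy experiments use 2 levels /
8 channels.

The loss is `similarity + λ·diffusion`, with MSE on normalized intensities by
default (a local windowed-NCC option exists; window 9 voxels) and the
diffusion term the mean squared forward-difference gradient of the
displacement components (normalized by 3N so it is grid-size independent);
λ defaults to 0.01. The similarity gradient with respect to the field is the
residual times the sampled spatial gradient of the moving image; inside the
training objective the warp uses clamp-to-edge sampling, because a
constant-fill boundary makes the objective discontinuous in `u` at the grid
faces (scipy assigns the entire boundary sample to the fill value for any
infinitesimal outward offset). Optimization is Adam (default lr 1e-2;
experiments use 3e-3), deterministic under a fixed seed.

Validation regime: 64×64×32 phantom pairs at 3×3×4 mm with couch removed.
The field must be resolvable *above the interpolation floor*: warping by even
the perfect field costs trilinear blur at tissue edges, so on too-coarse grids
(or too-small deformations) the best possible warp has a *higher* MAE than not
warping at all. At the chosen scale the ground-truth field reduces MAE by
about half, and 30 epochs of training reach that ceiling (≈ 50 % MAE
reduction on training pairs; held-out phantoms improve because the sag
component is systematic and predictable from the image). Serialized models
(npz weights + JSON provenance with the loss trace and pair manifest)
reproduce predictions bit-exactly.

## Image similarity

MAE, NCC and global SSIM are direct closed forms over the evaluation region
(optionally a mask; the pipeline uses the planning body mask). NCC is the
Pearson form with the 1/N normalization, so identical non-constant images
score exactly 1. SSIM uses the global-statistics form with
`c1 = (0.01L)²`, `c2 = (0.03L)²`, `L = 4095` (the CT range shifted
non-negative); identical images score exactly 1 by construction of the
numerator/denominator pairing. GMSD maps intensities linearly from
[−1024, 3071] HU to [0, 255] (the scale on which the stabilizer `C = 170` is
conventional), computes per-axial-slice 2D Prewitt gradient magnitudes
(1/3-normalized kernels, reflected boundary), forms the gradient-magnitude
similarity map, and reports its standard deviation over the region; identical
images give GMSD = 0 and a global intensity offset leaves it unchanged. All
four metrics are validated against brute-force loop/formula oracles at 1e−10
(1e−6 for the filtered GMSD).

## Sphere placement

The candidate region is the GTV eroded by the 10 mm contraction (exact
Euclidean distance transform with mm sampling) minus all voxels within 15 mm
of any OAR. A deterministic greedy sweep walks axial planes in order and
candidates lexicographically within each plane, accepting a candidate iff all
same-plane accepted centers are ≥ 60 mm away with the nearest ≤ 80 mm
(single-sphere planes are allowed), and all cross-plane centers are ≥ 30 mm
away in 3D. No randomness is involved; identical inputs give identical
sphere sets. Row offsets between nearby planes emerge from the 3D cross-plane
constraint rather than an explicit parity pattern. An infeasible geometry
returns an empty set carrying a structured warning, not an exception. The
audit recomputes every minimum with the same distance transforms plus
brute-force pairwise distances, so placement and audit cannot drift apart.
A 12 mm-radius GTV is *feasible* for a single sphere under these rules
(its center is 12 mm from the surface); infeasibility begins below a 10 mm
radius.

## Synthetic lattice dose

A stand-in for the treatment planning system. Inside the GTV the dose is a
`valley_ratio · prescription` plateau (default 0.35 × 2000 cGy); outside it
decays exponentially over 12 mm of EDT distance. Each sphere adds an isotropic
smoothstep kernel; its support radius is solved so that, for a continuous
uniform ball, a center peak of `peak_factor · prescription` (default 1.35,
inside the 120–150 % envelope expected of LRT sphere maxima) yields a median
of exactly the prescription, and the amplitude is then rescaled against the
discrete voxel median so the 1 % median contract holds on any grid. The field
is linear in the prescription. Limitations: no beam physics, no collimation
structure, no inter-sphere dose anisotropy.

## DVH engine and plan comparison

Cumulative DVHs use exact voxel-volume weighting with `V(d)` = fraction
receiving ≥ d. `Dx%` (and `DV-cc`) interpolate linearly between sorted voxel
doses on the cumulative hot-volume axis, with the convention that the
cumulative volume after the i-th hottest voxel is `(i+1)` voxel volumes;
Dmax/Dmin are point doses. MVS(d) is the absolute volume receiving strictly
less than d. Isodose sphere fitting thresholds at 50 % of *prescription*
(not of maximum), labels 26-connected components, drops components below
0.1 cc (speckle guard; the painter's smooth doses never trigger it), and
returns fixed 15 mm spheres at component centroids (mean voxel-center
position). Plan comparison forms per-structure, per-metric paired deviations
and applies the two-sided Wilcoxon signed-rank test (zeros dropped, exact null
for n ≤ 25 without ties via scipy, normal approximation with tie correction
beyond); all-zero difference vectors are reported as degenerate rather than
tested. The exact p-values are validated against full 2ⁿ sign-assignment
enumeration.

## Pipeline

`run_pipeline` executes a study-in-miniature: n seeded phantom cases (default
3 at 64×64×32, 4×4×5 mm), preprocessing, one model trained across cases,
per-case similarity reports (dCT-vs-pCT and sCT-vs-pCT over the body mask),
sphere placement + audit, synthetic lattice dose, DVH metrics evaluated
against both the original sphere contours and contours re-fitted from the
50 % isodose (the route used when one image set has no drawn spheres), paired
deviations between the two contour routes, and OAR limit checks (600 cGy
D0.03cc-type constraints; D1cc for skin; MVS floors for lung/liver). The JSON
report contains no timestamps and every number comes from a module operation,
so a rerun with the same config and seed is byte-identical. Problem sizes
were chosen so a full run completes in about a minute on a single CPU while
still exercising every stage at meaningful resolution.

## Known limitations

* The learning stage is CPU-scale by design; it demonstrates the mechanism
  (field prediction, warp, loss geometry) rather than clinical accuracy, and
  the phantoms' systematic-sag dominance is what makes generalization to
  held-out cases possible.
* Sphere placement maximizes count greedily; no global optimization or
  template matching is attempted, and plans with equal counts but better
  spacing are not searched.
* The dose painter is geometric, not physical.
* DICOM input, oblique affines, and 4D CT are out of scope; NIfTI (plus the
  JSON sidecar) is the interchange format.
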