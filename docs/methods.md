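# Methods

This note records the models, conventions, defaults and numerical choices
behind `periroi`, and what the synthetic experiments do and do not show.

## Conventions

Arrays are indexed `(z, y, x)`, 0-based, half-open ranges. Physical
coordinates are LPS millimetres; geometry metadata (`spacing`, `origin`,
3×3 orthonormal `direction`) is stored in ITK physical order `(x, y, z)`.
DICOM series are ordered by ImagePositionPatient projected on the slice
normal (robust to renumbered InstanceNumber exports). The classification
task is binary with luminal = 1 as the positive class; subtype strings in a
manifest (`Luminal`, `HER-2`, `Triple-negative`, ...) collapse to 1/0/0, so
sensitivity always refers to detecting luminal disease.

## Preprocessing

Per-volume z-score normalization uses the population (ddof = 0) standard
deviation over all voxels, which makes the two-voxel contract
{0, 2} → {−1, +1} exact and removes per-center global gain/offset without
any cross-case state. Resampling targets 1 mm isotropic (linear for images,
nearest-neighbour for masks; output size = round(extent/spacing), so
physical extent is preserved to within one voxel per axis). Bias-field
correction divides by a smooth strictly positive field estimated either by
ITK N4 (shrink factor 2, 3 × 20 iterations) or by a log-domain degree-3
polynomial least-squares fit; non-positive inputs are shifted internally
and the offset restored, so z-scored volumes are handled.

The default stage order is z-score → resample → bias-correct. Bias
correction conventionally precedes intensity normalization; because neither
order is uniquely right for multicenter DCE-MRI, the `bias_first` flag
switches to N4-on-raw → z-score → resample, and the order actually used is
part of the run config rather than an implicit assumption.

Numerical note: N4 is not exactly idempotent — re-running it on corrected
output still shaves ≈1% of residual field per pass (measured RMS ≈1% on a
48³ ramp phantom). The polynomial fit is idempotent to machine precision.
The tests assert these measured magnitudes.

## Peritumoral expansion

A voxel belongs to the expanded mask iff the Euclidean distance (in mm,
spacing-aware) from its center to the nearest tumor-voxel center is
≤ r. This is computed with an exact Euclidean distance transform of the
background, so expansion is deterministic, monotone in r, and agrees with a
brute-force pairwise-distance oracle voxel-for-voxel (tested on grids up to
15³ across radii and anisotropic spacings, with an ε = 1e−9 slack for
exact-boundary float comparisons). Expansion is intended to run on the 1 mm
resampled grid, where "4 mm" is well defined regardless of native
anisotropy. Parenchyma clipping is the automated intersection ring ∩
parenchyma; tumor voxels are always retained (with a warning if the
parenchyma mask misses them), and a `clipped` flag records whether any
shell voxel was removed. When no parenchyma mask is supplied, no clipping
occurs.

## Extraction

All five modes are framed by the minimum bounding cube of the *expanded*
mask: the tight per-axis box grown symmetrically to equal side lengths (odd
leftovers to the high side), optionally padded, clamped to the grid (the
`is_cube` flag records when clamping breaks cubicity). Deterministic tie
rules throughout: slice selection by in-mask area takes the lowest index on
ties; centroid indices round half-down (2.5 → 2). 2.5D2 uses channel
offsets {−k, 0, +k} with k = 2 by default — three channels rather than five
because the planar backbones consume exactly three — and clamps
out-of-range offsets to the mask's occupied axial extent, so a single-slice
lesion yields three identical channels (the clamp is recorded in
provenance). The 2D mode uses the axial (acquisition) view.

ROI_only writes `fill_value` outside the effective mask *after* z-score
normalization; the default 0 is then the cohort-typical intensity, avoiding
step artifacts at the mask border. Planar crops are resized bilinearly and
3D crops trilinearly to fixed backbone sizes without aspect preservation
(the cube crop keeps distortion minimal) and without anti-aliasing, so
resizing is the only lossy step; the pre-resize crops are retained on every
`Extraction` for oracle testing.

## Phantom generator

Each case is a centered ellipsoidal parenchyma (semi-axes 0.42 × grid
extent) at background level 100 with smooth Gaussian-filtered texture
(sd 5, correlation length 6 mm) plus white noise (sd 10), containing one
lesion: an ellipsoid with 4–8 mm semi-axes perturbed radially by a random
smooth quadratic-plus-linear form of direction (amplitude 15%), giving
lobulated margins that exercise bounding/centroid code beyond spheres.
Lesions enhance by +30; placement retries up to 100 times to stay inside
the parenchyma. The binary class signal is an additive mean shift of
effect_size × noise_sd (default 1.0), planted either inside the lesion or
in a 3–5 mm distance band outside it, with distances computed by the same
transform as the expansion operator. Class-1 prevalence defaults to 0.721,
the luminal fraction of the modelled population. Three "centers" (the
multicenter structure) apply per-center global gain (0.9–1.1) and offset
(±10); cohorts default to the ≈25/39/36% train/val1/val2 split.
Determinism: one global seed streams per-case seeds through
`SeedSequence.spawn`, so cases regenerate independently of order.

The default 48³ grid at 1 mm isotropic holds the largest lesion plus an
8 mm expansion with margin; it is a desk-scale stand-in, not a
clinical-resolution breast volume. An additive mean shift (not texture) is
the default signal because it keeps the Bayes-optimal separability
analytically controllable: the shell-mean statistic recovers a planted
peritumoral signal (AUC ≈ 1 at effect 1.0, n = 100) while staying at chance
for intratumoral signal, which pins the signal's location model-free.

What the phantoms do **not** emulate: MR acquisition physics (coil
sensitivity, k-space artifacts), realistic parenchymal architecture,
lesion texture heterogeneity, segmentation error, or correlations between
lesion size and class. Passing tests therefore demonstrate that the
pipeline recovers signal where it was planted under controlled conditions —
not clinical-level performance.

## Classification harness

`build_dataset` stacks one extraction per manifest case in sorted-case_id
order and freezes per-channel standardization statistics computed on the
train cohort only; validation cohorts always reuse them. Augmentation
(90%-side random crop + resize, horizontal/vertical flips; for 3D patches,
flips along every axis) is seeded per sample and applied only during
training.

The default backbone, `small_cnn`, is a compact CNN implemented in pure
NumPy (float64, im2col convolutions): two conv(3×3)+ReLU+avg-pool blocks
(8 and 16 channels), global average pooling, and a 1-logit linear head,
trained with Adam (decoupled weight decay available) on binary
cross-entropy, with optional inverse-prevalence class weighting and early
stopping on a train-loss plateau. Pure NumPy makes training bit-reproducible
per seed on any CPU, and the whole configuration grid runs in minutes. An
`resnet50_imagenet` backbone (final layer replaced by a 1-logit head) is
exposed through the same registry for full-scale work; it imports
torch/torchvision lazily and is not exercised by the test suite. For grid
runs, per-cell seeds derive from the base seed and the cell's position in
sorted order, so partial grids reproduce full-grid cells.

Desk-scale experiment sizes, chosen once as the package's study conditions:
200-case cohorts (120 train / 80 validation), 32×32 planar inputs (16³
volumetric), 20 epochs at learning rate 1e−2. The directional-recovery
experiment (signal in a 3–5 mm shell; compare validation AUC of (2.5D1,
4 mm, ROI original) against (2.5D1, 0 mm, ROI only)) reproducibly favors the
context-seeing configuration, and shows no such advantage when the signal
is intratumoral.

## Statistics

AUC is the tie-corrected pairwise statistic, computed via midranks
(equivalent to the Mann–Whitney formulation; verified against exhaustive
pair enumeration). DeLong variance/covariance use the structural-component
estimator with sample (ddof = 1) variances; CIs are normal-approximation,
clipped to [0, 1], degenerating to a point interval (with a warning) when
the variance is zero at AUC ∈ {0, 1}. The paired test returns z = 0, p = 1
for identical score vectors. Operating points use the Youden-optimal
threshold (ties → lower threshold) chosen on the training cohort and frozen
for validation cohorts; score ties at a threshold are treated as positive
(≥ t). Decision curves use NB(t) = TP/n − FP/n·t/(1−t) on a default
threshold grid 0.01–0.99 (step 0.01; t = 1 excluded as the weight
diverges). Calibration uses 10 equal-width bins; empty bins report count 0
with NaN frequency and are never interpolated. Grid reports order modes
2.5D1, 2.5D2, 2.5D3, 2D, 3D and optionally attach paired DeLong z/p against
a named reference cell. DeLong-based CIs are used throughout for
consistency with the paired comparisons (bootstrap is available only as a
test oracle).

## Known limitations

- The harness trains one model per grid cell with a single train/validation
  split; cross-validation is out of scope.
- The 3D backbone path is the compact CNN only; no pretrained 3D weights
  are shipped or downloaded.
- Expansion is Euclidean, not geodesic: it can cross anatomical boundaries
  unless a parenchyma mask clips it.
- Bias-field correction assumes a smooth multiplicative field; it will not
  fix structured artifacts.
- Phantom realism is deliberately limited (see above); absolute AUCs on
  phantoms say nothing about clinical cohorts.
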