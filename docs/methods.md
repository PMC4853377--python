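# Methods

`serialrecon` reconstructs 3D volumes from serially sectioned brain image
stacks and registers a labeled template volume onto them.  This note
describes the models and procedures, the parameters that matter, what the
synthetic phantom does and does not emulate, and the numerical choices made
where the design was open.

## Problem setting

Cutting a brain into sections destroys the 3D coherence of the stack: every
mounted section carries an unknown rigid motion plus smooth non-linear
deformation.  Blockface photographs — images of the frozen block taken
before each cut — are geometrically undistorted per-slice references.  The
pipeline therefore (1) reconstructs the blockface stack into a reference
volume, (2) aligns each distorted section to its blockface slice with a
modality-specific strategy, and (3) registers a labeled template (an
MRI-based atlas stands in here) onto the blockface volume so its labels can
be carried into the reconstructed data.

Conventions: world coordinates are mm with origin at the corner of the
first voxel (`world = index * spacing`), `z` is the sectioning axis, and all
resampling transforms map fixed (output) coordinates into moving (input)
coordinates.  2D alignment estimators return forward motions
(section → reference); resampling uses their inverse.  The one exception is
the PLI refinement, whose B-spline stage is not invertible in closed form;
it returns resampling maps directly.

## Blockface reconstruction

Phase one detects the circular chuck fiducials (threshold at a configurable
fraction of the dynamic range, connected components, intensity-weighted
sub-pixel centroids, row-major ordering with a marker-sized quantization of
the row key so ordering is stable under jitter) and translates every slice
so its mean marker centroid matches slice 0.  This removes chuck/camera
repositioning jitter exactly, but not the *perspective error*: tissue and
markers lie at different heights, so the tissue can be offset relative to
the markers by a slice-dependent amount.

Phase two aligns each slice to a running median of the stack along z, where
those offsets behave as outliers.  Two implementation choices matter:

* The detected fiducial disks are blanked before phase two.  They are
  already exactly aligned, so their (bright, high-contrast) pixels would
  otherwise pin the tissue in place.
* The per-slice reference is a *leave-one-out* median (the public
  `median_volume` operation keeps the plain definition).  Wherever the
  tissue geometry changes monotonically along z — at the poles of any
  convex brain — the centre slice is the tie-breaking vote of its own
  window, so a self-inclusive median reproduces the very offset it is
  supposed to remove.  A slice whose neighbours carry no tissue falls back
  to the self-inclusive median.

The SSD translation search is exhaustive over integer shifts (±15 px by
default), restricted to the dilated foreground of the reference slice, with
a quadratic sub-pixel fit; it is computed for all shifts at once via FFT
cross-correlations.  Slices whose reference has fewer than 100 foreground
pixels or negligible foreground/background contrast pass through unrefined.

Accuracy at phantom scale (96×96×64, jitter ±3 px, sparse perspective
offsets ±2 px, 2% noise): mean per-slice translation error 0.33–0.41 px
across seeds, strictly better than the marker phase alone.  On slices with
cross-sections above ~1/8 of the frame the error stays below 1 px; smaller
pole sections sit at a 1–2 px stochastic floor, because with only ~50
slices the geometry change inside a median window rivals the offsets and
boundary votes occasionally flip.  This is a phantom-scale artifact: at
real stack sizes (>1000 sections) the per-window geometry change is
negligible.  Brain masking uses a 3D watershed on the Gaussian gradient
magnitude, seeded from background/foreground intensity quantiles (defaults
0.50 / 0.92), keeping the largest foreground basin, closed and hole-filled.

## Section-to-blockface alignment

* **Histology** (full-contrast tissue): tissue masks by Otsu threshold +
  largest connected component + closing; the binary mask centres of gravity
  are superimposed; an exhaustive rotation search (default 0.5° steps over
  ±180°, ties resolve to the smallest angle) minimizes the SSD about the
  blockface COG.
* **Autoradiography**: receptor-free structures appear as zero-signal
  "empty regions", which corrupt area-based criteria (a hole shifts the
  mask COG; a band can split the mask so the largest component is half a
  brain).  The stack is first made internally coherent by chaining rigid
  fits of scale-invariant (SIFT) keypoint matches between consecutive
  sections, then anchored to the blockface through landmark-derived rigid
  transforms on every K-th section (default every 10th at phantom stack
  sizes; the parameter is the anchor spacing), linearly interpolated in
  (θ, tx, ty) with angle unwrapping in between; outside the anchor range
  the nearest anchor is held.  The rigid fit from keypoint matches uses an
  exhaustive 2-point-hypothesis consensus (score every pair hypothesis by
  its inlier count at a 1.5 px threshold, refit the best consensus by least
  squares, then one 3×-median rejection round and a final refit).  Smooth
  tissue textures make SIFT descriptors repetitive enough that a plain
  least-squares fit with a single rejection round diverges; the consensus
  step makes individual gross mismatches harmless.  When fewer than two
  stable matches survive, the step falls back to COG alignment.
* **PLI** (orientation-coded, 3-channel): the scalar signal is the value
  channel (channel maximum) — hue encodes fiber direction and must not
  drive intensity metrics.  COG initialization, a coarse ±15° SSD rotation
  sweep (near-circular sections leave the MI gradient too flat to pull in
  several degrees), rigid registration on Mattes mutual information, then a
  cubic B-spline with a fixed 5×6 control grid minimizing SSD, restricted
  to the union of the two tissue masks.  A stage that leaves its metric
  worse than its initialization is dropped and flagged, as is a B-spline
  whose maximum control displacement exceeds half the grid spacing
  (fold-over territory).

All strategies skip sections with fewer than `min_tissue_px` (default 50)
tissue pixels; landmark fits are closed-form 2D orthogonal Procrustes
(demean, SVD of the cross-covariance, rotation without reflection, then
translation).

## Template registration and label propagation

The template is masked to its labeled voxels (label 0 = background) and
registered onto the blockface volume in three stages of increasing freedom
— rigid, affine, cubic-B-spline free-form deformation — each initialized
with the previous stage's result and each run over a Gaussian pyramid
(default 6 levels, factor-2 downsampling, smoothing sigma = shrink/2, with
the coarsest level clamped so the smallest image axis keeps ≥8 voxels).
The optimization engine is SimpleITK.  Metric settings `NMI`/`MI` use
Mattes mutual information (32 bins) as the optimization objective; a 32-bin
normalized-mutual-information value is computed in-repo on the full-
resolution images before and after every stage, logged in the chain's
provenance, and used as the degradation guard: a stage that worsens it is
discarded and flagged.  Rigid and affine stages use gradient descent with
automatic learning-rate estimation, physical-shift parameter scaling, a
capped physical step, and seeded random sampling (25%); the B-spline stage
uses LBFGSB over seeded random samples (10%) with the control grid
parameterized by spacing in fixed-image voxels (default 20; this is the
grid-flexibility axis of `grid_sweep`).  Runs are single-threaded and fully
deterministic for a fixed config.

Structure exclusion (the olfactory-bulb situation: a structure whose
position in the sectioned data does not reflect its true position) is a
fixed-image mask built from labels: all foreground minus the excluded
structures and minus the z-slices they dominate.  It is *applied* by
blanking voxels outside the mask to background before optimization rather
than through the engine's metric-mask facility, which proved brittle at
phantom scale (sharp but narrow masked optima; stages consistently
diverged from cold starts).  When a mask is used without an explicit
initial transform, a quick unmasked rigid pre-alignment plays the role the
manual anchoring step plays in practice.  Labels are always propagated
with nearest-neighbour interpolation, so the propagated label set is a
subset of the template's.

## Evaluation

Dice coefficient `2|A∩B|/(|A|+|B|)` on voxel sets; average surface distance
and Hausdorff distance on surface voxel point sets (a voxel is surface when
a face-neighbour — 6-connectivity, configurable — lies outside the mask;
array borders count as outside), with nearest-neighbour distances via a
KD-tree, which is exact (the distance-transform shortcut is unnecessary at
these sizes).  Conventions for degenerate inputs: two empty segments are an
error for all three measures; one empty segment gives Dice 0 and is flagged
in reports; distances require both surfaces non-empty.  The common 0.7
"good match" level is exported as a constant for reporting, never enforced.
The ambiguity of whether the ASD normalizer counts surface or volume voxels
is resolved to surface point sets, matching the "discrepancy of the
surfaces" reading; the volume-normalized alternative would only shrink the
values.

## The phantom

`make_scene` builds an ellipsoidal "brain" (label 1) with an internal
hippocampus-like ellipsoid (label 2, always intersected with the brain so
nesting holds by construction) and a bulb-like spherical appendage at one
pole (label 3).  Intensities are per-structure base levels plus two
Gaussian-filtered noise textures, both smooth along z (σ=6 voxels; real
receptor/cell densities vary slowly from section to section, and the
feature-based strategy depends on neighbouring sections sharing structure)
with coarse (σ=2 in-plane, amplitude 0.09) and fine (σ=1, amplitude 0.05)
in-plane scales.  Defaults: 96×96×64 voxels at (0.05, 0.05, 0.06) mm —
echoing the real acquisition scales while staying minute-scale to compute.

Rendered artefacts and their recorded ground truth:

* **Blockface**: per-slice translation jitter (uniform ±3 px), sparse
  perspective offsets (30% of slices, uniform ±2 px — sparse because the
  median scheme presumes outlier-like offsets), four corner fiducial disks
  that move with the jitter only, 2% additive Gaussian noise.  Slice 0 is
  the reference camera frame (zero jitter/offset), so the reconstructed
  space coincides with the truth frame.
* **Sections**: independent per-slice rigid motions (|θ| ≤ 10°, |t| ≤ 10%
  of the field), optionally a smooth random 2D warp (PLI default 1.5 px);
  autoradiographs get a squared (wider-range) intensity map and the
  internal structure zeroed on even-indexed sections by default — exactly
  where naive SSD matching of consecutive sections is stressed; PLI
  sections are HSV-coded with hue from a synthetic swirl direction field.
  Synthetic landmarks (bounding-box corners of the tissue pulled toward
  the COG, jittered by 0.3 px to emulate manual placement) are attached to
  every 10th section.
* **Template**: the truth resampled through a known affine (fixed default
  parameters within scales 0.9–1.1, rotations ≤ 10°, translations ~4% of
  the extent — fixed rather than seed-drawn so the rigid-vs-affine gap is
  guaranteed) composed with a smooth cubic-B-spline warp (control spacing
  16 voxels, coefficient σ = 2 voxels), a monotone intensity remap
  (square root) standing in for the MRI modality gap, and 1% noise.  An
  optional appendage shift adds a displacement bump to the warp control
  points near the bulb, emulating its preparation-induced dislocation.

All randomness flows through explicit seeds; no global random state is
touched.  What the phantom does **not** emulate: staining/exposure
inhomogeneity, tears and folds, anisotropic section compression, true
polarimetric signal formation, and inter-subject anatomical variability.
Passing tests therefore demonstrate the correctness and the failure-mode
behaviour of the algorithms, not their performance on real tissue.

## Problem sizes used in tests

Unit tests run on 64×64×48 phantoms; end-to-end and acceptance checks on
the default 96×96×64.  A full three-stage registration takes ~60–90 s
single-threaded at that size; the acceptance script's rigid+affine run
~30 s.  The empty-region regression uses an internal structure widened into
a transverse band (~50% of the tissue area) so that both documented failure
modes of area-based alignment — COG displacement and mask splitting — are
present; the separate-strategy comparison is evaluated as alignment Dice
(each section's true tissue mask carried through the recovered transform),
since intensity-threshold overlap would conflate the correctly-empty band
with misalignment.

## Known limitations

* The per-slice 1–2 px stochastic floor of the median refinement on small
  cross-sections (see above) — negligible at real stack sizes.
* The feature-based intra-stack chain needs ~10+ reliable keypoint matches
  per consecutive pair; at 64-voxel frames the phantom carries too little
  texture for that, so the autoradiograph strategy is validated at the
  default size only.  The chain accumulates drift between anchors; anchor
  spacing trades manual effort against drift.
* Normalized mutual information is the reported and guarded metric, but
  the inner optimization objective is Mattes mutual information; for
  single-pair registrations their optima coincide in practice.
* B-spline registration is not diffeomorphic; fold-over is only guarded
  against in the 2D PLI refinement.
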