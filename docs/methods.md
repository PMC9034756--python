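# Methods

## Coordinate model

The atlas is a 3D integer annotation volume in fixed AP × DV × ML axis
order (loaders transpose any declared on-disk order). On the Allen CCF
10-µm 2017 grid the volume is 1320 × 800 × 1140 voxels. Stereotaxic
positions are mm relative to a configurable bregma voxel, default
(AP 540, DV 0, ML 570) following the SHARP-Track convention for that
grid; the convention is a field, not a constant, because published AP
values only make sense relative to whichever origin a lab adopts. The
sign table (anterior, right, dorsal positive) is documented in
`atlas_model` and is the single source of truth; `mm_to_index` and
`index_to_mm` are exact inverses.

Oblique virtual sections model off-axis cutting: the normal-axis
coordinate at canvas pixel (r, c) is

    base + tan(ml_tilt)·(c − c_center) + tan(dv_tilt)·(r − r_center)

with half-up rounding to the nearest voxel. Labels are sampled
nearest-neighbor — they are categorical, and interpolation would
fabricate ids. Pixels sampling outside the volume carry label 0 and a −1
sentinel in the per-pixel coordinate map. With both tilts zero the
section is bit-identical to direct array slicing. The coronal canvas is
fixed at 800 × 1140 (10 µm/px); other planes default to the volume face,
and a `canvas_shape` override exists so toy volumes can use matching
smaller canvases.

## Cells as points, not masks

Counted cells are carried as float (x = column, y = row) pixel
coordinates and transformed analytically through every geometry step
(downsample, pad, landmark warp). This is mathematically the same mapping
as warping a binary cell mask, but preserves multiplicity when two cells
fall into one 10-µm pixel, which a binary mask cannot. A mask export
(`points_to_mask`, half-up rounding) exists for compatibility; the
quantification path never uses it. Conservation is an invariant: every
tally total equals the number of ingested coordinates, with out-of-brain
cells kept in a first-class "outside brain" row (id 0) rather than
dropped.

## Preprocessing

Images are rescaled by f = pixel_size / atlas_voxel (area averaging;
exact block means when 1/f is integral, anti-aliased resampling
otherwise) and centered on the canvas with symmetric zero padding. The
original workflow fills borders without stating placement; centering is
our choice, and the recorded `CanvasRecord` (scale, offsets) makes every
downstream result independent of it and inverts the mapping to < 1e−9 px.
Contrast is a parametric per-channel linear stretch (quantile or absolute
bounds) applied before downsampling; it never changes geometry.

## Registration

Landmark pairs come from a CSV contract (idx, slice_x, slice_y, atlas_x,
atlas_y) — the one substantive interface change needed to make the
workflow headless, replacing interactive clicking. Families: affine
(≥ 3 pairs), projective homography (≥ 4, the default — the landmark
workflow this follows is homography-like), and thin-plate spline (≥ 4,
regularization 0, for local tissue deformation). Fitting is least squares
via scikit-image estimators; strict mode (default on) additionally
requires 10 pairs, turning the workflow's strong recommendation into an
enforced, overridable validation. TPS interpolates its landmarks exactly
up to linear-solver precision (~1e−5 px at canvas scale — sub-nanometer
physically). Degenerate configurations (collinear or duplicated slice
points) are rejected.

Images are warped by inverse mapping with bilinear resampling (the TPS
inverse is a spline fitted on the swapped pairs); points are mapped
forward through the identical transform, which is what keeps warped cells
glued to warped tissue. Transforms serialize to versioned JSON: matrices
for affine/projective, the landmark pairs for TPS (the spline is re-fitted
deterministically on load, so the round trip reproduces the mapping
bit-exactly without depending on solver internals being serializable).

## Quantification

Atlas-frame cell pixels are half-up rounded (sub-pixel region borders are
below atlas resolution), traced through the section's coordinate map to a
3D voxel, and resolved through the structure tree. Counts are reported at
the annotation's leaf label; a one-level roll-up is an optional view.
Sagittal quantification under the Chon variant is rejected, mirroring the
upstream restriction. Point edits (add/move/delete, polygon group
delete/translate with boundary-inclusive membership, self-intersecting
polygons rejected) apply in order, are logged with timestamps for
provenance, and trigger re-assignment when applied to an assigned record.

The two-ontology comparison computes Pearson r on paired per-slice
totals, a paired t on structures per slice (zero-variance differences
give t = 0 by convention), per-atlas means/SDs, and nomenclature overlap
by exact name matching — the matching rule the source workflow used is
not documented, so exact matching is implemented and flagged as such.

## Synthetic fixtures

The generator emulates the study's demonstration material: toy volumes of
nested ellipsoidal regions inside a brain ellipsoid (the outer mask is
seed-independent so the allen/chon variants share a brain but disagree on
internal borders and names), sections rendered back to acquisition
resolution (default 0.5 µm/px, the stated resolution of the workflow's
example images) as 16-bit Gaussian blobs over noise, FIJI-dialect
coordinate files, and ≥ 10 exact landmark pairs on the tissue outline.
Cells are sampled ≥ 3 voxels inside their region's in-plane border so
that small registration error cannot flip their assignment. Ground-truth
transforms are near-identity projective maps (±3° rotation, ±4% scale,
±2.5 px translation, mild perspective). All randomness flows through one
seeded generator; identical seeds reproduce files byte-for-byte.

What the fixtures do **not** emulate: optical PSF, channel bleed-through,
tissue autofluorescence, torn or folded tissue, and ventricle-size
mismatch. Passing tests therefore demonstrate the geometry and accounting
are correct, not that landmark placement on real, imperfect histology
will be as accurate; on real data registration quality depends on the
user's landmarks, exactly as in the interactive original.

## Problem sizes and numerical choices

Tests and the acceptance script run on 60 × 100 × 140 toy volumes with
100 × 140 canvases and 180–250 cells per check — comfortably large enough
that every region keeps a ≥ 3-voxel interior while each full-pipeline run
stays near a second. The preprocessing-geometry check uses a
full-resolution 4000 × 5600 synthetic image to exercise the real 20×
downsample onto the 800 × 1140 canvas. Half-up rounding is used
everywhere a float coordinate meets a grid (stated because banker's
rounding would differ on exact halves). Out-of-range indices, empty point
sets, empty tally lists, and all-zero volumes are valid inputs with
defined results, not errors.

## Known limitations

- Mouse atlases only; no non-mouse species, no atlas editing, no
  hierarchy visualization.
- No cell detection: counting happens upstream, and only its coordinate
  output is parsed.
- No intensity-based or automatic registration; landmarks are the
  contract, by design.
- The Chon variant is modeled as a voxel-wise annotation on the same
  10-µm grid with its own tree; per-section overlay distributions are not
  supported.
- Real-data comparison statistics across a whole brain (dozens of slices)
  depend on the experimenter's material and are out of scope; the
  statistic computation itself is implemented and tested on synthetic
  tables.
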