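# Methods

This note documents the models, procedures and design choices behind
`canalseg`, in the order data flows through the pipeline.

## Coordinate conventions and I/O

All stages work in one canonical frame: axis 0 = x (left-right), axis 1 =
y (anterior-posterior, anterior at low index), axis 2 = z
(inferior-superior); an axial slice is a fixed z. NIfTI volumes are
reoriented to the closest RAS frame at read time; DICOM series are
accepted only in axial identity orientation and sorted by slice position.
Bounding boxes are 0-based and half-open, so crops compose without
off-by-one ambiguity. Intensities stay floating point throughout — CBCT
units are scanner-arbitrary and uncalibrated — and every histogram
operation first applies a min-max 256-bin quantization. Halving a volume
uses linear interpolation for intensities, nearest neighbour for masks,
and ceil for odd extents so no slice is ever discarded.

## Synthetic phantom

The phantom is parametric rather than atlas-based: the tests need analytic
ground truth, not realism. A parabolic arch (axial cross-section, band of
half-thickness 0.07·nx around the curve) extruded over the lower ~quarter
of the volume forms the mandibular body; two elliptic-cylinder rami rise
from the arch ends to just below the maxilla. An exact Euclidean distance
transform splits each bone into a cortical shell (default 1 mm, ≥2 voxels
at the default grid) and a trabecular interior. Fourteen tooth ellipsoids
sit on the superior arch surface; a second, slightly narrower arch above a
configurable air gap (default 4 mm) plays the maxilla; a 0.5 mm
soft-tissue envelope surrounds all bone; zero-mean Gaussian noise
(σ = 0.015 on a [0,1] intensity scale) is added last, from the
configuration seed.

Each canal is a tube of radius 1.4 mm (2.8 mm diameter, inside the
clinically reported 2–3 mm range) around a natural cubic spline through
five on-arch control points, descending from a superior-posterior entry on
the medial ramus (the mandibular-foramen analogue) to an anterior exit
(mental-foramen analogue), monotone in the anterior direction. Piecewise
cubics are used instead of a single four-point Bézier because a Bézier
does not interpolate its inner control points and would cut the arch
corner out of the bone band; segment-wise the curve is still cubic.
Generation fails loudly if the tube (lumen + rim) leaves the mandible.

Intensity ladder (defaults): air 0.0 < soft tissue 0.06 < trabecular 0.35
< rim 0.58 ≤ cortical 0.62 < tooth 0.95, with the canal lumen at 0.33 —
deliberately *within noise of the trabecular level*. In cone-beam scans
the nerve/vessel contents of the canal are hard to tell from marrow; the
thin cortical rim is the feature that makes the canal detectable, and the
phantom encodes exactly that: with `rim_thickness_mm = 0` the canal is
nearly invisible, which is what the learning benchmark demonstrates. The
ladder and the 0.5 mm soft-tissue envelope were chosen so that, with zero
noise, the exact 3-level Otsu optimum groups the histogram as
{air, soft, lumen-free low end} | {trabecular} | {cortical, rim} |
{teeth}; this was verified against the brute-force variance search, since
near-ties between candidate splits are decided at the 1e-7 level.

Geometry scales with the grid (fractions of the field of view); canal
radius, rim, shell and gap are physical (mm). The default grid,
160×160×128 at 0.4 mm, keeps every test CPU-cheap; the densification
study uses the same 64 mm field of view at scanner resolution
(320×320×256 at 0.2 mm).

What the phantom does **not** model: beam hardening, scatter, partial
volume at boundaries (tissue assignment is hard), textured trabecular
bone, patient variability, metal artefacts. Tests passing on the phantom
therefore show algorithmic correctness and qualitative behaviour, not
clinical-grade accuracy.

## Mandible ROI extraction

The panorama is a maximum-intensity projection along the
anterior-posterior axis. A curved dental-arch reformation would be more
faithful to clinical panoramas; the MIP preserves the structures the
pipeline needs (tooth row, corridors, maxilla band) and the
`col_to_x` column map isolates the choice so a curved projection can be
swapped in later.

Thresholds come from the exact 3-level Otsu (float64 maximisation of
between-class variance by dynamic programming over the 256-bin histogram;
ties resolve to the lowest cuts): teeth = third level of the panorama's
central third, bone = first level of the tooth-height band. Manual
overrides replace either threshold.

Steps, with the numerical choices that are not forced by the procedure:

* Tooth row: binarise the central third at the teeth threshold, dilate by
  1 mm (disk, via exact EDT), keep the largest component.
* Tooth-height band: the z rows of the tooth object, padded 1 mm
  *downward only* — the tooth object is already dilated upward, and
  padding the top would open an air sliver above the occlusal level that
  competes with the buccal corridors in the next step.
* Corridors: complement of the bone binarisation within the band, two
  largest components (component ties resolve to the lowest label, for
  determinism).
* Maxilla cut: everything above the top of corridors ∪ tooth row, per
  panorama column; columns inside the union's span without content take a
  linearly interpolated cut height, columns outside the span are not cut.
  A strict per-column rule would leave the maxilla untouched over columns
  lateral of the teeth.
* 3D: binarise at the bone threshold, delete voxels above the per-column
  cut, close with a 2 mm ball, keep the largest 3D component. The last
  step exists because noise produces isolated supra-threshold voxels that
  a closing cannot remove and that would otherwise inflate the bounding
  box to the whole volume.
* Crop to the bounding box and fill voxels outside the mandible mask with
  the volume minimum (air), a neutral value for any downstream
  thresholding.

All morphology uses Euclidean distance transforms with physical
`sampling`, equivalent to ball/disk structuring elements of the given
radius in mm, exact under anisotropic spacing, and linear-time in the
volume regardless of radius.

On the default phantom the resulting box holds 100 % of the canal,
excludes the maxilla entirely, and covers ≈0.25 of the input volume.

## Annotation densification

Tracings are extracted from RGB overlays by per-channel color matching
with a configurable tolerance (monotone: a larger tolerance can only add
pixels). Sparse annotations are slices along the anterior-posterior axis
— the canonical axis closest to the clinical cross-sectional annotation
direction for an arch-following canal; slicing axially instead would put
the near-horizontal canal almost parallel to the slice planes, where no
per-pixel interpolation along the axis can reconstruct it. The axis is a
parameter. The emulated protocol starts at the first canal-containing
slice and continues to the end of the volume at the chosen interval (a
tracer confirms the canal has ended by annotating empty slices beyond
it).

Densification fits a natural cubic spline per (row, col) pixel through
the {0,1} slice values, clamps to [0,1] to suppress cubic overshoot,
thresholds at 0.5 (symmetry), and reproduces annotated slices exactly.
At least four slices are required (cubic support). On the
scanner-resolution phantom, 1 mm annotations densified to the 0.2 mm grid
recover the analytic tube at Dice 0.950, degrading monotonically to
≈0.90 at 2 mm and ≈0.84 at 3 mm intervals.

## Networks and training

Three families share one numpy engine (stride-1 N-D convolution, 2×
max-pooling with stored argmax indices, index-based unpooling, 2×
transposed convolution, batch norm, dropout, Adam); every layer passes a
finite-difference gradient check at ~1e-9 relative error.

* `segnet2d`: 13-conv VGG16 encoder, plan
  (64,64)(128,128)(256,256,256)(512,512,512)(512,512,512), batch norm,
  mirrored decoder driven by the stored pooling indices, 1×1 output conv;
  ≈29.5 M parameters at the canonical plan.
* `unet2d`: 4-down/4-up double-conv U-Net with 'same' padding, so feature
  maps keep the input size and no crop precedes the skip concatenation.
  Channel plans (64…1024) "original" (≈31.0 M parameters) or (32…512)
  "fewer filters" (half plan — the halving is this package's choice; no
  counts are published for the small variant). Adjacent-slice context is
  extra input channels on one shared network: a=2 slices per side gives
  5 input channels and changes nothing else. Dropout (0.5) sits at the
  bottleneck.
* `unet3d`: the 3D counterpart with three resolution steps — the depth at
  which a 132³ valid-padding input is arithmetically consistent (sizes
  132→128→64→60→30→26→13→9, then 18→14, 28→24, 48→44) — batch norm,
  no dropout, valid padding kept; skips are centre-cropped before
  concatenation. 64 random 132³ patches per volume are the sampling
  default, with optional centre-cropping of the mask to the 44³ valid
  output region.

`build_model` also emits a declarative per-layer description (output
shapes and parameter counts, computed analytically); an incompatible
input size raises an error naming the first failing layer. A
name-matched `.npz` loading hook exists for externally pre-trained
encoder weights; no weights ship with the package and the hook is not
validated against any published checkpoint — all tests train from random
initialisation.

Class weights use median frequency balancing,
`freq(c) = pixels(c)/(images containing c · image size)`,
`weight(c) = median(freq)/freq(c)` (for two classes the median is the
mean of the two frequencies). The rare canal class is upweighted; the
orientation of any published background:canal ratio follows from that
(small weight on the frequent background class). The loss is weighted
binary cross-entropy on the 2-class softmax output with probabilities
clipped at 1e-7. With Adam, "momentum" is taken as the first-moment
coefficient β1 (0.9), since Adam has no classical momentum term; the
"decay" of the 2D recipes is applied multiplicatively,
`lr/(1 + decay·epoch)` (the semantics are not published), while the 3D
recipe's step schedule divides the rate by its factor after every period
(5e-4 → 1e-4 after epoch 5). Splits are floor-based (test and valid take
`floor(n·r/Σr)`, train the remainder): 49 094 items at 6:2:2 give a
9 818-item test partition. Stratified mode applies the ratio within each
label group. Best-on-validation checkpointing restores the parameters of
the lowest-validation-loss epoch.

## Desk-scale learning benchmark

A tiny 2D U-Net (filters 8/16/32, batch norm on, dropout off) trains for
200 Adam steps (lr 3e-3, batch 4) on anterior-posterior phantom slices
cropped to the mandible region (128×96), split 6:2:2, with
median-frequency class weights, and is scored by standard canal IoU over
the held-out slices. Batch 4 was chosen because smaller batches leave the
precision of the rare class unsettled within the fixed 200-step budget on
some seeds; the sizes keep the full benchmark — two trainings — around
four minutes on one CPU. Typical results: loss falls by ~98 %, clear-rim
IoU ≈0.63–0.85 across seeds, rim-free IoU ≈0.20–0.58 — always lower than
clear-rim, reproducing the qualitative rim-dependence the phantom was
designed to encode. The direction is asserted, not the magnitude.

## Evaluation

Confusion counts treat canal as positive. Two metric formulations are
first-class: *printed* (per-class pixel accuracy as precision,
TP/(TP+FP) and TN/(TN+FN); canal IoU = TP/(FN+TP+TN), background IoU =
TN/(FP+TN+TP)) and *standard* (recall-style accuracies; IoU =
TP/(TP+FP+FN)). The printed forms reproduce the arithmetic of the
published comparison table; the standard forms exist for external
comparability; global accuracy and class accuracy (mean of the two
per-class accuracies) coincide across variants. Reports carry their
variant and raw counts; zero-denominator metrics are NaN, never 0. When
TN ≥ FP the printed canal IoU is a lower bound on the standard one
(denominator dominance).

## Known limitations

* The ROI pipeline is validated on the phantom geometry; heavily rotated
  heads, edentulous jaws or scans whose tooth row leaves the central
  third of the panorama would need the manual threshold overrides or a
  curved-arch projection.
* Densification interpolates along one canonical axis; true
  arch-perpendicular cross-section geometry is not modelled.
* The numpy engine is single-threaded and CPU-bound; the canonical-size
  networks instantiate and give correct shapes/parameter counts, but
  training them at published scale is out of scope.
* Phantom realism limits are listed above; in particular the benchmark's
  IoU numbers say nothing quantitative about clinical data.
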