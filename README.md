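# canalseg

Automatic mandibular canal segmentation tooling for cone-beam CT (CBCT).

The inferior alveolar nerve (IAN) runs through the mandibular canal, a bony
channel lined by a thin cortical rim. Locating it is a prerequisite for
implant planning, third-molar extraction and orthognathic surgery, and is
normally done by tracing cross-sections by hand. `canalseg` implements an
end-to-end pipeline for automating that task on CBCT volumes:

* **Mandible ROI extraction** — a panorama-guided procedure that isolates
  the 3D mandibular region: multi-level Otsu thresholds (bone = first
  level, teeth = third), tooth-row detection on the central third of the
  panoramic projection, buccal-corridor detection, per-column maxilla
  removal, 3D morphological closing, and a masked bounding-box crop. The
  result is roughly a quarter of the original volume.
* **Annotation densification** — clinician tracings are color-keyed masks
  on cross-sections at ~1 mm intervals; a per-pixel cubic interpolation
  along the slice axis (clamped to [0, 1], thresholded at 0.5) restores the
  scanner's 0.2 mm interval.
* **Trainable encoder-decoders** — 2D SegNet (VGG16 encoder, decoding by
  stored max-pooling indices), 2D U-Net in the 'same'-padding variant with
  no pre-concatenation crop (original or halved filter plans, optional
  adjacent-slice input channels), and a 3D U-Net with valid padding, batch
  norm and no dropout (132³ patches → 44³ outputs). Implemented on a small
  numpy engine with explicit backprop and Adam, so everything runs and is
  testable on a CPU.
* **Class balancing and training options** — median frequency balancing
  (`weight(c) = median(freq)/freq(c)`) for the weighted binary
  cross-entropy (the canal occupies <1 % of the voxels), seeded 6:2:2
  train/valid/test splits, random 3D patch sampling, step and
  multiplicative learning-rate decay, best-on-validation checkpointing.
* **Evaluation** — confusion counts plus five metrics in two variants:
  the *printed* formulation (pixel accuracy as precision TP/(TP+FP); canal
  IoU = TP/(FN+TP+TN), a denominator that includes true negatives) and the
  community-*standard* one (recall-style accuracy; IoU = TP/(TP+FP+FN)).
  Every report is stamped with its variant; undefined ratios are NaN.
* **Synthetic phantom** — a seeded, fully parametric CBCT-like volume
  (parabolic mandibular arch with cortical shell and trabecular interior,
  two canals on smooth cubic paths with configurable rim thickness, teeth,
  a maxillary arch above an air gap, Gaussian noise) with analytic
  ground-truth masks, so the whole pipeline is exercised without clinical
  data.

## Worked example

```python
from canalseg.phantom import PhantomConfig, generate_phantom
from canalseg.mandible_roi import extract_mandible_roi
from canalseg.evaluation import evaluate_run

sample = generate_phantom(PhantomConfig(seed=1))
roi = extract_mandible_roi(sample.volume)
print("thresholds:", [round(t, 3) for t in roi.thresholds.levels])
print("box:", roi.box.lo, roi.box.hi)
canal = sample.canal_mask.data
print("canal voxels inside ROI box:",
      f"{canal[roi.box.slices].sum() / canal.sum():.1%}")
print("ROI fraction of volume:",
      f"{(roi.cropped.data.size / sample.volume.data.size):.2f}")
```

prints

```
thresholds: [0.054, 0.68]
box: (12, 14, 14) (147, 141, 63)
canal voxels inside ROI box: 100.0%
ROI fraction of volume: 0.26
```

i.e. the automatically chosen bone/teeth thresholds isolate a box that
contains the entire canal while discarding about three quarters of the
volume (the maxilla, the air above it, and the margins).

The command line mirrors the library:
`canalseg phantom|roi|densify|split|train|eval --help`.

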