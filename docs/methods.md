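# Methods

## The problem and the pipeline

Elaiosome phenotyping from seed photographs has one central difficulty: the
elaiosome's cream color is nearly identical to the bright stripe pattern on
the seed coat, so color thresholding alone mis-segments a large fraction of
seeds. The pipeline therefore (1) separates seeds from a blue background and
standardizes them into fixed-size crops, (2) trains a detector on a small
labeled set, and (3) grows the training set semi-automatically by keeping
only the detector's verified-correct predictions and retraining, stage by
stage. Evaluation uses the standard instance-segmentation metric suite, and
the final masks feed a 10-trait morphometric layer.

## Synthetic scenes

The generator (`seedsynth`) emulates top-down photographs of non-touching
seeds on a uniform blue background. Its defaults define the study
conditions used throughout the tests:

- scene: 1024 × 1024 px, 100 seeds (tests use 450–900 px scenes with 12–50
  seeds to keep runtimes small; the geometry per seed is identical);
- seed shape: an ellipse (major axis 42–62 px, minor 20–30 px, uniform) with
  the polar radius modulated by a 2-term Fourier series (relative amplitudes
  1–5 %, ≤ 8 % of the minor axis), giving a convex-hull deficit so solidity
  is below 1 as in real seeds;
- elaiosome: a half-ellipse lobe capping one apex, clipped to the seed; its
  area fraction is driven to a uniform draw from (0.06, 0.14) by bisection
  on the lobe length (real lines average roughly 4–8 %; the default range
  brackets the upper part of that span because at these raster sizes a
  smaller lobe is only a few hundred pixels and the morphological
  post-processing becomes discretization-dominated);
- stripe: with probability 0.7 (1.0 in confounder studies), a quadratic
  Bézier band of width 2–4 px along the coat, drawn in a bright cream
  within a small jitter of the elaiosome color and excluded from the
  elaiosome mask — this reproduces the color-confusion failure mode;
- palette: background (30, 60, 160), coat (72, 46, 26), elaiosome
  (224, 208, 168), stripe (235, 222, 186); additive Gaussian pixel noise
  σ = 4 applied last, clipped to [0, 255];
- placement: rejection sampling with a 2 px minimum gap; a bounded number
  of attempts, then an explicit density error;
- randomness: one stream per scene derived from (seed, scene index), so
  scenes are order-independent and every output is byte-reproducible.

What the generator does **not** model: photorealistic texture, shading,
camera optics, touching or overlapping seeds, debris, and natural
within-line color variation. Passing tests therefore demonstrate the
correctness and the qualitative dynamics of the pipeline (segmentation
exactness, protocol improvement, confounder behavior), not field
performance on photographs.

## Preprocessing

Segmentation happens on the U (blue − luma) channel of BT.601 YUV: the
background is strongly positive, seed pixels near zero or negative. The
default threshold is Otsu's split refined by one Lloyd step (midpoint of the
two class means) — on noise-free synthetic scenes all coat pixels share one
U value and the raw Otsu bin center can fall inside that cluster's own
histogram bin. Holes are filled and components under `min_area_px` (32)
dropped. Crops expand the tight bbox by 5 %, paint non-seed pixels with the
chosen background variant (black / configured blue / white), pad to square,
and resize to 170 × 170 (bilinear for the image, nearest for the mask, so
masks stay binary); the non-seed region of a finished crop equals the
variant color exactly.

## Baseline detector

The trainable baseline is a two-class Gaussian color model in YUV over
seed-interior pixels: per class (elaiosome / rest-of-seed) a maximum-
likelihood mean and full covariance (regularized with εI, ε = 10⁻³ of the
mean variance), priors from class pixel frequencies, per-pixel posterior
thresholded at 0.5. Post-processing: morphological opening (disk radius 7
at crop scale — wide enough to erase stripes, which scale to ≤ ~10 px in
upsampled crops), keep the largest surviving component of ≥ 24 px, then
reconstruct it inside the thresholded region **bounded to within the
opening radius of the component**. Unbounded reconstruction re-absorbs a
stripe whenever a one-pixel blend bridge connects it to the lobe; bounding
recovers the opening-eroded boundary ring without that failure mode. The
detection score is the mean posterior over the kept pixels; one detection
per crop at most (one elaiosome per seed).

The detector sits behind a minimal `fit`/`predict` contract; a deep
instance-segmentation network can replace it without touching the protocol,
either in-process or through a JSON-lines detection exchange (documented in
`detector.py`).

## Self-training protocol

Stage 0 trains on `stage_sizes[0]` ground-truth-labeled crops (default
sizes 10/20/40/80 — a desk-scale stand-in for the 100/200/3000/6000 regime
of a production run). Each later stage predicts on the entire pool, selects
"correct" predictions — automatically (score > 0.5 **and** mask IoU with
the reference > 0.9, reusing the similarity cutoff) or via a user accept
list standing in for manual checking — samples its stage size from the
selection (all of it when fewer are available, with a logged warning),
retrains from scratch, and is evaluated on a fixed held-out split.
Retraining from scratch rather than fine-tuning keeps the baseline exactly
reproducible. Stage comparison uses
`similarity = ycount / (ycount + ncount)`: per reference detection, IoU of
the paired masks > 0.9 counts toward ycount, anything else — including a
missing detection in the other set — toward ncount.

A note on why the protocol improves at all with a closed-form model: the
selected pseudo-labels are the model's own masks, whose boundaries sit on
the posterior-0.5 color contour. They are more color-consistent than
ground-truth masks (whose boundaries carry resize blend noise), so each
round sharpens the class model and widens the selectable pool. The
held-out mask AP50:95 median over 5 protocol seeds rises monotonically
across the four stages under the default synthetic conditions.

## Evaluation metrics

Pixel confusion counts are accumulated over whole crops (predictions below
score 0.5 contribute all-negative masks), which is why specificity and
accuracy sit near 1: a 170 × 170 crop is mostly true-negative background.
AP follows the all-point interpolation
`AP = Σ (R_{n+1} − R_n) · max_{r ≥ R_{n+1}} p(r)` with COCO-style greedy
one-to-one matching (descending score, ties broken by annotation id,
deterministic), reported in percent, swept over IoU thresholds
0.50:0.05:0.95 for both box and mask IoU; mAP is the per-class mean (one
class here). The implementation is tested to 10⁻⁹ against an exhaustive
max-scan oracle.

## Morphometrics

Traits follow common particle-analysis conventions: equivalent-moment
ellipse axes (full lengths), AR = Major/Minor, circularity = 4πA/P²,
roundness = 4A/(πMajor²), solidity = A/convex-hull-A, elaiosome area and
its percentage of seed area. Lengths scale by `mm_per_px` and areas by its
square when provided; the default unit is pixels.

Perimeter needs care on rasters: a raw pixel-edge (staircase) boundary
overestimates a disk's perimeter by ~27 % and any local chain-code
correction that fixes the disk breaks exactness on rectangles. The chosen
estimator traces the exact pixel-corner boundary polygon and simplifies it
with Douglas–Peucker at 2.0 px. This is exact for axis-aligned rectangles
(the corner polygon is already minimal), within ~1 % on disks and
ellipses, and rotation-stable to under ~1.5 % — the tolerance 2.0 px was
selected by measuring anisotropy across rotated reference ellipses. The
same corner-polygon tracer backs the COCO polygon conversion, where
round-trips through even-odd rasterization are pixel-exact.

Per-line summaries are unweighted means over a line's seeds; descriptive
statistics over lines report mean, max, min and the sample (n − 1) standard
deviation and require at least two lines.

## Numerical and design choices

- Coordinates are 0-based, half-open, bbox = (x, y, w, h), matching COCO.
- All randomness flows through `numpy` `SeedSequence`s keyed by (seed,
  index), so every artifact is reproducible byte-for-byte from one integer.
- The 8:1:1 split operates at image level (largest-remainder allocation,
  exact sizes) to prevent leakage of near-identical crops across parts.
- Canonical COCO serialization (sorted keys, 4-decimal floats) makes
  write → read → write byte-identical.
- Undefined ratios (zero denominators) are reported as NaN, never as 0.
- Degenerate inputs raise explicit errors: empty masks, degenerate bboxes,
  overcrowded scenes, insufficient labeled pixels (< 10 per class),
  all-zero confusion counts, empty reference sets.

## Problem sizes

The test suite and the acceptance script use scaled problem sizes chosen as
the smallest that exercise the full dynamics: 200-crop pools (4 scenes ×
50 seeds), stages 10/20/40/80, 5 protocol seeds for the improvement
property, 10–30 scene batches for segmentation and confounder regressions.

## Known limitations

- The color-model baseline cannot separate elaiosome from stripe pixels by
  color alone; it relies on morphology, so stripe geometries wider than the
  opening radius would defeat it. A shape-aware detector behind the same
  contract is the intended upgrade path.
- Touching seeds are out of scope (no watershed separation).
- Trait absolute values are in pixels unless `mm_per_px` is calibrated;
  comparisons across imaging setups require that calibration.
- Perimeter (hence circularity) carries a small rasterization bias on
  smooth shapes (≲ 1–2 %); tolerances in the tests account for it.
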