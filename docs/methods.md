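# Methods

`periscan` implements a two-stage pipeline for grading peri-implantitis
damage on periapical radiographs: locate each dental implant's threaded
region, split the implant into its two clinically assessed sides, and
classify each side as damaged or healthy. Because clinical periapical
films are not redistributable, the package ships a ground-truthed
synthetic-radiograph generator and demonstrates parameter recovery on
it; every stage also works on real annotated images supplied in the
same PNG + JSON format.

## Synthetic radiographs (`periscan.synth`)

Each image is a noisy gingiva/bone background (default mean 90,
per-pixel Gaussian noise sd 10, plus a weak smoothed low-frequency
field at 15% of the noise amplitude with a 6 px correlation length)
with one or more bright implant shafts (default intensity 220). A shaft
is a smooth collar (two thread pitches tall) above an alternating
crest/trough band pattern orthogonal to the shaft axis: crests extend
the half-width by 3 px, troughs inset it by 2 px, at a 12 px pitch.
This produces the periodic edge structure the gradient-based
enhancement keys on. The shaft axis is rotated by up to ±5° so the
midline-regression stage is actually exercised.

Damage is rendered as a triangular erosion wedge abutting the coronal
threads of one side: widest at the platform, tapering to nothing after
`defect_depth_threads` pitches (default 3), darkening the background by
`defect_darkening` gray levels (default 60; the recovery study uses
80). A half is labeled damaged exactly when a wedge was rendered on
that side; the exact wedge and shaft masks are kept on the
`AnnotatedImage` so downstream stages can be scored against rendering
truth. Ground-truth boxes cover only the threaded region — the damage
signal lives at the first thread, and boxing the whole implant body
would drown it.

Intensity choices were made once, for contrast ordering rather than
photorealism: shaft ≫ background ≫ wedge, with the noise scales chosen
so that the wedge-vs-mirrored-region contrast reproduces
`defect_darkening` within a few gray levels on essentially every seed.
What the generator does *not* emulate: real bone trabeculation,
neighbouring teeth and crowns, film exposure gradients, implant brand
geometry, overlapping anatomy. Passing the synthetic recovery study
therefore shows the pipeline's machinery is sound — not that the
trained weights transfer to clinical films.

Determinism: one `numpy` generator seeded from the spec drives all
draws; identical spec + seed reproduces images bit for bit. Dataset
generation derives per-image seeds from a master seed and assigns the
requested damaged fraction exactly over half-labels.

## Thread detection (`periscan.detect`)

The detector is a single-class grid network in the YOLOv2 family:
3×3 conv / batch-norm / leaky-ReLU(0.1) blocks, five stride-2 max
pools, one stride-1 "same" pool, two wider blocks, and a 1×1 head
emitting `n_anchors × (5 + n_classes)` channels per cell — with the
default five anchors and one class, a 13×13×30 map for a 416×416×3
input. `detector_layer_table` exposes every activation shape for audit.

Training minimizes the usual multi-part squared error: sigmoid x/y
offsets and log-space w/h against the responsible anchor
(λ_coord = 10), objectness pushed to 1 at responsible anchors
(λ_obj = 5) and to 0 elsewhere (λ_noobj = 0.5). Anchor priors come from
seeded k-means over training boxes with 1−IoU distance. The optimizer
is SGD with momentum 0.9 and global gradient-norm clipping at 10,
which the squared-error objective needs for float32 stability. No
validation split is consumed; the trace records one loss per
iteration, and iterations follow the floor convention
`iterations/epoch = ⌊dataset/batch⌋` with trailing partial batches
discarded.

Two numerical choices matter on synthetic data. First, the reduced
desk-scale profile (`demo_detector_config`: 128 px input, channel
widths 8…48, 24 epochs, batch 8, lr 0.01) uses a **single anchor**:
synthetic implants share one box shape, and spreading responsibility
over five near-identical priors starves each coordinate head of
training signal (recall plateaued near 0.8 with five anchors and
reaches ≈0.97 with one). The full-scale default keeps five. Second,
inference decodes boxes at `conf_threshold` (default 0.5), then
applies greedy NMS at IoU 0.5; NMS is configurable off to reproduce
the known duplicate-detection failure mode on incomplete implants.

Detection is scored as a 2×2 matrix: greedy one-to-one matching by
descending confidence at IoU ≥ 0.5 (configurable); unmatched implant
truths are false negatives, predictions matching a separately
annotated tooth region (or nothing) are false positives, unclaimed
tooth regions are true negatives.

## Cropping and half-splitting (`periscan.crop`)

Thread boxes are widened horizontally by 20 px per side (configurable;
the adjacent gingiva carries the damage evidence), clipped silently at
image borders. The implant is extracted by Otsu binarization (largest
connected component; a uniform crop raises), and the midline is the
ordinary least-squares fit of column on row over foreground pixels —
the implant is near-vertical, so regressing across rows recovers the
centerline without any rotation step. The crop is cut row by row at
the midline (a pixel centre exactly on the line goes left), and both
halves are zero-padded on the cut edge to the width of the wider one,
so left/right pairs share dimensions and the split is a lossless
partition (`merge_halves` is an exact inverse). Zero padding was
chosen over replication; the padded columns read as background.

## Enhancement (`periscan.enhance`)

Global histogram equalization uses the plain scaled cdf,
`out = ⌊255·cdf(g)⌋`, with **no** cdf-minimum renormalization — hence a
constant image maps to 255. The adaptive variant is a hand-rolled
CLAHE sharing that convention: per-tile clipped histograms
(clip limit as a fraction of tile pixels, excess redistributed
uniformly), tile mappings blended bilinearly between tile centres,
clamped to the nearest tile outside the centre grid. With one tile and
clip 1 it reduces exactly to the global operator — a property the test
suite exploits. Defaults: 8×8 tiles (shrunk for small halves), clip
0.01.

The absolute difference of the two equalized images is overlaid onto
the original by pixel-wise maximum (the stated intent is boundary
enhancement; max preserves both the bright implant and the difference
ridges). The gradient-magnitude surface of the overlay (central
differences inside, one-sided at borders) supplies edge evidence.
Labeling order: a pixel below the gum/background gate is background
regardless of anything else; otherwise a pixel whose local min–max
gradient range (3×3 window) exceeds the range threshold is an edge;
remaining flat pixels split into implant (above the implant/gum
threshold) and gum. All three thresholds default to Otsu splits
computed from the image itself (range threshold from the gradient
ranges, implant/gum from flat-pixel intensities, gate from flat pixels
below that) and can be pinned in `SurfaceParams`. Coloring: implant
green (0,255,0), gum orange (255,165,0), background black, edge pixels
keep their overlay gray, and a pure red reference line marks the
platform row — by construction the top row of the thread crop, where
erosion reaching the first thread shows up.

## Classification (`periscan.classify`)

The classifier is an AlexNet-style CNN with a 450×250×3 input — tall
like a half-implant crop, so inputs are neither stretched to a square
nor buried in padding. (An aspect-preserving resize with symmetric
zero padding performs the fit; both distortion and over-padding are
documented failure modes.) Stem 11×11 stride 4 → 110×60×96, then the
classic grouped-conv/LRN/pool sequence down to 12×6×256, and a compact
head 1152 → 144 → 2 with dropout 0.5 (value unstated upstream; the
conventional default) at both FC dropouts. `width_scale` shrinks all
widths proportionally for the desk-scale profile
(`demo_classifier_config`: 150×80 input, scale 1/8, 20 epochs,
lr 4e-3 — the full-scale schedule of lr 6e-5 over ≥50 epochs is
impractical for a from-scratch CPU run).

Dataset assembly: classes are balanced by down-sampling the majority
(only when further than 5% from 1:1 — mirroring reference counts where
a 162:164 imbalance is left alone), split 80/20 stratified, and the
training portion augmented ×4 with horizontal/vertical flips.
Augmenting after the split guarantees the validation set contains no
flip-variant of any training image. The learning rate follows the
stepped schedule `initial × 0.75^⌊(epoch−1)/30⌋`. Training keeps
trailing partial batches (matching the reference iteration counts of
81 per epoch for 1304 images at batch 16).

## Evaluation (`periscan.evaluate`)

2×2 matrices are reported in the clinical-table layout: counts with
percent-of-total in parentheses, per-row subtotals (precision for the
positive row), per-column subtotals (the two recalls), overall accuracy
in the corner. Display rounding is half-up to one decimal percent; raw
values are always retained and are what tests compare. Ratios with a
zero denominator are flagged `None`, not raised. Rendered tables parse
back losslessly. The negative class is "Healthy"/"Tooth" throughout,
matching column order. One published subtotal (the tooth-column 78%) is
not derivable from its own cells (89/104 = 85.6%); the package reports
the derivable value.

## The scaled recovery study

`periscan.cli.synthetic_study` defines the desk-scale end-to-end
conditions in one place: 200 synthetic radiographs with strong defect
contrast (darkening 80) at a 1:1 damage ratio; the reduced detector
trained on 100 and scored on the held-out 100 (IoU ≥ 0.5 recall); 400
ground-truth halves enhanced and split 80/20, the reduced-width
classifier trained 20 epochs, accuracy measured on the 80 held-out
halves. On one CPU the study runs in roughly three minutes and
typically yields detection recall ≈ 0.97 and held-out classification
accuracy ≈ 1.0 — comfortably above the 0.9 / 0.85 targets — plus
high-confidence (> 0.9) damaged calls on very strongly eroded halves.
These numbers characterize the synthetic conditions, not clinical
performance.

## Known limitations

- The CNNs run on a small in-package numpy layer library with manual
  backprop; it is deliberately minimal (no GPU, no autograd) and the
  full-scale 416/450-input configurations are buildable and auditable
  but not practical to train here.
- The synthetic generator's simplifications (above) mean classifier
  weights trained on it carry no clinical validity.
- Mesial/distal naming is not attempted — film orientation and tooth
  quadrant are not encoded — so halves are reported as left/right.
- Multi-class detection, ROC analysis, and DICOM ingestion are out of
  scope.
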