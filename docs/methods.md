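# Methods

## Problem and model

`ewenet` detects ewe estrus **mounting behaviour** — one animal climbing
onto another's hindquarters, the visual signature of estrus — in frames
from a fixed overhead barn camera (2560×1440). The detector is a
one-stage, anchor-based convolutional network in the YOLO-v3 family with
two structural changes motivated by the viewing geometry:

1. **Four detection layers.** Animals far from the camera occupy few
   pixels. Beyond the usual 13×13 / 26×26 / 52×52 output grids (at
   416×416 input), a fourth stride-4 head on a 104×104 grid is fed by
   upsampling the 52-scale branch and concatenating it with the stride-4
   backbone feature, so shallow high-resolution information reaches a
   prediction layer. Each head predicts, per cell and per anchor,
   `(x, y, w, h, c)` plus M class scores; with four heads the model
   emits `3·(13² + 26² + 52² + 104²) = 43,095` candidate boxes per image
   (10,647 for the three-head pyramid).
2. **Deeper final stage.** The backbone is a Darknet-53-style residual
   network whose five stages hold (1, 2, 8, 8, 6) residual units — two
   more units in the last stage than the original (1, 2, 8, 8, 4) — to
   compensate for the extra fusion path. A residual unit is a 1×1
   bottleneck followed by a 3×3 convolution with an additive skip; every
   convolution is followed by batch norm and leaky ReLU(0.1). At full
   width (64…1024 channels) the model has ≈73 M parameters (≈292 MB in
   float32), consistent with the published model-size scale.

Channel widths on the 104 path are not specified by the architecture's
description; we follow the pyramid's halving convention (route 256→128,
concat with the 128-channel stride-4 feature, 5-conv block at width 128).

## Anchor clustering

Anchors are re-derived from the label boxes by K-means++ under the
similarity-based distance `d(q, p) = 1 − IOU(q, p)`, where IOU is the
*shape* overlap of width/height pairs placed at a common centre
(position is irrelevant for priors). The objective is
`f = Σ_q (1 − max_p IOU(q, p))`. Choices:

* **Centre update:** per-cluster arithmetic mean of member (w, h), with
  a monotonicity guard — the mean minimises squared distance, not 1−IOU,
  so a candidate mean is accepted only when it does not raise its
  cluster's cost. This keeps the objective non-increasing at every
  iteration (asserted in tests) and can only improve on the plain mean
  update.
* **Restarts:** K-means++ seeding is stochastic; 10 restarts are run and
  the lowest objective kept. On 8-sample instances this provably reaches
  the optimal partition found by exhaustive search.
* **k = 12:** the average best-IOU curve rises with k and levels off;
  twelve anchors, three per head, is the operating point. The twelve
  published cluster centres are shipped (`MOUNTING_CLUSTER_CENTERS`) and
  reproduce the published pixel anchor table exactly when multiplied by
  416 and rounded.
* **Layer assignment:** anchors sorted by ascending area (ties by
  width), triples handed to the heads finest-first. The published
  assignment is not strictly area-sorted (its rows 4 and 5 swap), so the
  literal published map is also shipped as a constant
  (`MOUNTING_LAYER_MAP`) and used as the default anchor set.

`IoUKMeans` implements this as a scikit-learn estimator
(`fit`/`predict`/`transform`, `cluster_centers_`, `inertia_`,
`avg_iou_`).

## Preprocessing

* **Letterboxing.** A source frame (w₂, h₂) is scaled by
  `s = min(w₁/w₂, h₁/h₂)` to (w₃, h₃) = (round(w₂s), round(h₂s)) and
  centred on a (w₁, h₁) canvas with offsets `dw = (w₁−w₃)//2`,
  `dh = (h₁−h₃)//2`; padding is exactly RGB (128, 128, 128). For
  2560×1440 → 416×416: (w₃, h₃, dw, dh) = (416, 234, 0, 91). Odd pad
  remainders go to the right/bottom. Boxes map affinely
  (`x → xs + dw`); the inverse map restores them within 0.5 px.
* **Masking.** Regions of the frame where mounting cannot occur are
  blanked by filling everything outside a configured keep-polygon.
* **Augmentation.** Horizontal flip, horizontal/vertical shifts
  (default up to ±10% of the frame; shifted boxes are clipped and
  dropped when less than 25% of their area stays visible), and
  brightness scaling (darken U(0.6, 0.9), brighten U(1.1, 1.4), clamped;
  boxes untouched). Magnitudes are package defaults — the source
  material shows the augmentations only qualitatively.
* **Frame sampling** keeps one frame in every `stride` (default 3),
  starting at index 0.

## Targets and loss

Each ground truth is assigned to the single anchor (over all 12, across
heads) with the highest shape IOU; the responsible cell is the one
containing the box centre at that head's stride. Regression targets are
the YOLO parameterisation: `σ(tx), σ(ty)` are the centre offsets within
the cell and `tw = log(w/anchor_w)`, `th = log(h/anchor_h)`.

The loss, summed over the four heads and averaged per image:

* coordinates — sum-squared error on `(σ(tx), σ(ty), tw, th)` at
  positive cells, weight 5;
* objectness — binary cross-entropy with logits, weight 1 on positives
  and 0.5 on negatives; a *dynamic ignore region* exempts non-responsible
  predictions whose decoded box overlaps a ground truth with IOU > 0.5.
  (A static, anchor-shape-based ignore was tried first and rejected:
  slots that never receive gradient drift to high confidence with
  untrained box regression and survive NMS as false positives.)
* class — binary cross-entropy at positive cells.

Gradients are computed analytically inside the loss; the rest of the
network uses the `ewenet.nn` reverse-mode autograd (im2col convolution,
batch norm, leaky ReLU, nearest-neighbour upsampling, concatenation),
every backward pass of which is verified against central finite
differences in the test suite. The prediction head's objectness bias is
initialised to −4 (a low-objectness prior) to stabilise early training.

## Training and model selection

SGD with momentum 0.9, weight decay 5e−4 (convolution kernels only),
constant learning rate 1e−3, batch size 10, 100 epochs — only the
initial rate is specified by the reference regimen, so no schedule is
applied. One checkpoint is written per epoch; validation P/R/F1 (at
confidence 0.5) and mAP are logged per epoch, and the working model is
chosen post hoc as the epoch with the best F1, ties broken by mAP and
then by the later epoch. A single seed covers weight initialisation,
shuffling and augmentation.

## Evaluation

Greedy one-to-one matching by descending confidence; a prediction is a
TP iff its best still-unmatched ground truth has IOU ≥ 0.5 (PASCAL
convention — the matching threshold is a package choice, config-exposed).
Duplicate detections count as FPs. P = TP/(TP+FP), R = TP/(TP+FN),
F1 = 2PR/(P+R), with P = R = F1 = 0 conventions for empty denominators.
AP is the area under the precision envelope of the P–R curve over all
confidence cuts (all-point interpolation, not 11-point); mAP is the mean
over classes and equals AP here because there is a single class. The
confidence-threshold sweep uses a 0.00–1.00 grid with step 0.05.

On a fixed prediction set, recall is provably non-increasing in the
confidence threshold. Rising precision — the trend reported for the
trained detector — is *not* a theorem under one-to-one matching
(discarding a low-confidence TP can lower precision); it holds when the
ranking is calibrated, i.e. correct detections outscore strays, which is
how the property is tested.

## Synthetic scenes

The original footage is not redistributable, so the generator fabricates
geometrically faithful stand-ins: mounting events are two overlapping
ellipses with distinct shading (the mounted animal brighter, offset onto
the other's rear) annotated with one box; single-ellipse distractors get
no annotation. Two real-data properties are reproduced deliberately:
a perspective size gradient (boxes shrink toward the top of the frame;
the mean box area in the top third is strictly below the bottom third),
and a four-prototype width/height distribution straddling the four head
scales after letterboxing (default prototypes span the published anchor
range, ≈19×34 to ≈92×122 at 416), so anchor clustering has recoverable
structure and target assignment exercises every head. Everything is
deterministic per (seed, index).

What the generator does **not** emulate: occlusion between animals, real
illumination and texture, motion blur, or fine-grained postural
variation. Passing tests therefore demonstrate the correctness of the
geometry, the optimisation and the metric stack — not transfer to real
barn footage.

## Problem sizes used in tests

The full-width 416-input network is exercised for construction and
parameter accounting, while training-path tests run a narrow variant
(`ArchitectureSpec.tiny`: 64-pixel input, stage widths 8–128, identical
four-head topology and (1,2,8,8,6) residual stages). The learnability
check trains on eight generated 128×128 scenes (two events, three
distractors each) with the reference SGD hyperparameters at batch 4 and
requires training mAP ≥ 0.9 within 200 epochs; it typically converges
between epochs 60 and 160 in well under a minute. Anchor-recovery runs
cluster ≈500 boxes from 170 scenes. These sizes are the package's
desk-scale stand-ins for the full 5,600-image experiment, which requires
the unpublished footage and GPU-scale training.

## Known limitations

* The numpy backend is single-threaded BLAS-bound; full-width 416 input
  runs at ~10 s per forward pass, so it is suitable for correctness
  work, not production inference.
* One behaviour class is assumed throughout the defaults (M = 1);
  multi-class plumbing exists but is untested beyond unit level.
* The mask polygon of the original installation is not digitised; masks
  are user-supplied.
* Checkpoint files are plain `.npz` weight archives; no cross-framework
  compatibility.
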