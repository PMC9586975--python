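# Methods

## The stacking model

`stackbox` is a two-level ensemble for bounding-box localization. The
level-0 models are M ≥ 2 object detectors, treated as black boxes that
emit, per image, boxes `(x_min, y_min, x_max, y_max)` with confidence
scores in [0, 1]. The level-1 model is a set of four independent
regressors, one per corner coordinate; each maps the M base learners'
values of that coordinate to a refined value. No joint 4-coordinate or
multi-output model is used — the four fits are deliberately separate,
which keeps the least-squares variant closed-form and makes each
coordinate's correction interpretable as an inverse of the detectors'
per-coordinate distortions.

### Training

1. **Matching.** For every ground truth, independently for every model,
   the same-image same-class detection with the highest IoU is selected,
   provided IoU > `min_iou` (default 0, i.e. any positive overlap).
   Matching is non-exclusive: one detection may serve several ground
   truths. No Hungarian assignment is attempted — each row only needs a
   representative of each detector's view of that object.
2. **Filtering and imputation.** Ground truths matched by no model are
   dropped. In the remaining rows, each empty slot is filled with a copy
   of the row's highest-IoU match, regardless of which model produced it
   (ties broken toward the earlier roster position, so the procedure is
   deterministic). Fill flags record which slots are imputed.
3. **Coordinate datasets.** Four aligned design matrices (n rows × M
   columns, column order = roster order) with the ground truth's
   coordinate as target.
4. **Fit.** One regressor per coordinate. The default backend is
   ordinary least squares in closed form (pseudoinverse, so a
   rank-deficient design — e.g. identical base learners — degrades
   gracefully to the minimum-norm solution); AdaBoost, random-forest and
   gradient-boosting backends come from scikit-learn, XGBoost is
   optional. All backends are seeded.

### Inference

There is no ground truth at test time, so each detection of each model
serves as a pseudo-ground-truth ("anchor") in turn: the best-IoU
detections of the remaining M−1 models fill the row (the anchor fills
its own slot), anchors with no match in any other model are dropped, and
missing slots are imputed from the row's best *non-anchor* match.
Mutually-best-matching detections produce identical rows from different
anchors; duplicates are removed by exact coordinate-tuple equality
(duplicates arise from symmetric matching of the very same detections,
so exact comparison is appropriate). The four regressors predict one box
per row; predictions that come out degenerate (min ≥ max on an axis) are
dropped with a logged count. Finally NMS at IoU 0.5 removes redundant
outputs.

The confidence of a stacked box is not defined by the level-1 model
(which regresses coordinates only); it is taken as the mean of the row's
slot confidences, imputed slots included, with the maximum as an option.
The mean mirrors how weighted boxes fusion treats confidence and keeps
the final NMS meaningful.

### Anchor-dropping and the recall ceiling

Dropping anchors without any cross-model support filters false positives
very effectively (random false positives rarely coincide across
detectors) but also discards objects found by exactly one detector. With
independent per-model miss rate r, the achievable recall is
1 − rᴹ − M·rᴹ⁻¹(1−r); at M = 3, r = 0.1 this is ≈ 0.973. This is a
property of the method, visible in the synthetic experiments.

## Fusion baselines

* **NMS** — greedy score-descending selection, suppressing boxes whose
  IoU with a kept box exceeds the threshold (default 0.5).
* **Soft-NMS** — scores decay instead of being suppressed: gaussian
  `s·exp(−iou²/σ)` (σ = 0.5) applied to every remaining box, or linear
  `s·(1−iou)` applied only above the IoU threshold; boxes whose score
  falls below 0.001 are removed. The σ and score-floor defaults follow
  the original Soft-NMS conventions.
* **NMW** — clusters seeded greedily in score order; fused coordinates
  are the mean of member coordinates weighted by `score × IoU(member,
  seed)`; the fused confidence is the seed's unchanged score.
* **WBF / WBF-max** — incremental clustering against the running
  confidence-weighted mean box; fused coordinates `Σ sᵢcᵢ / Σ sᵢ`;
  fused confidence the member mean (max for WBF-max), rescaled by
  (#distinct contributing models)/M by default. Per-model weights are
  supported and default to 1.

Ties everywhere break by (confidence desc, roster order, input order),
so every method is deterministic. All methods fuse independently per
(image, class).

## Evaluation suite

Ten metrics: AP@[.5:.05:.95], AP@.50, AP@.75, AP_M, AP_L, AR_1, AR_10,
AR_M, AR_L and mAP@.50 (class-averaged AP@.50; identical to AP@.50 on a
single-class dataset). AP uses 101-point interpolation: the precision
envelope max{p : recall ≥ r} sampled at r = 0, 0.01, …, 1. Matching is
greedy and one-to-one in confidence order, each detection taking the
unmatched ground truth with the highest IoU ≥ threshold (ties: first
index). AR averages recall over the ten thresholds 0.50:0.05:0.95 after
truncating each image to its top-1/top-10 (100 for the size buckets)
highest-confidence detections.

Size buckets follow the COCO convention (medium 32² ≤ area < 96², large
≥ 96², configurable): off-bucket ground truths are *ignored* rather than
counted, detections matched to them are neither TP nor FP, and unmatched
detections whose own area is off-bucket are excluded from the false
positives. Bucket metrics with no ground truths are reported as absent,
not zero.

The fold summary is the arithmetic mean ± sample SD (ddof = 1) per
metric across folds.

## Synthetic study conditions

The generator replaces GPU-trained detectors in all tests. Ground-truth
boxes are placed uniformly on 640×640 frames (the training resolution of
the motivating application), 1–3 boxes per image, areas log-uniform over
2 000–38 000 px² so the sample spans the medium and large size buckets,
aspect ratios uniform in [0.6, 1.6]. Boxes are rejection-sampled to
pairwise IoU ≤ 0.2 within an image — overlapping ground truths would be
merged by any 0.5-IoU NMS and are unrealistic for the application. A
placement margin keeps boxes away from the frame edge so that a biased
re-emission is never clipped (clipping would break the affine model and
bias coefficient recovery).

Each simulated base learner re-emits each ground truth with probability
1 − miss_rate, distorting every coordinate as `a_k·c_k + b_k + N(0,
jitter_sd²)`, and adds Poisson(fp_rate) false positives per image with
the ground-truth size distribution. Confidences are Beta-distributed
(concentration 25) with mean 0.85 for true detections and 0.30 for false
positives. All sampling uses named substreams of a single seed (gt, one
per model, fp), so adding a model never perturbs the ground-truth draw.

Presets:

* **perfect** — 3 identity learners, zero noise, 200 images. The whole
  pipeline must reproduce its input exactly (one output box per ground
  truth at IoU 1, mAP@.50 = 1).
* **bias** — 3 learners with *distinct, same-direction* affine biases
  (pure shift +12/+10 px; scale 1.03 with offset +5/+6; asymmetric
  inflation +6/+10/+24/+28), jitter 2 px, miss rate 0.1, 0.5 false
  positives per image, 500 images (used as 400 train / 100 test). The
  same-direction choice is essential to the regime being modelled:
  detectors that share a localization weakness. If the biases cancelled
  in the mean, confidence-weighted averaging (WBF) would already recover
  the truth and there would be nothing for a meta-learner to add. Under
  these conditions the base learners score mAP@.50 ≈ 0.2–0.66 and
  AP@.75 ≈ 0–0.06, WBF improves localization only marginally, and the
  least-squares stack reaches mAP@.50 ≈ 0.88–0.94 — qualitatively the
  ordering observed with real detectors on the motivating dataset. One
  departure: here WBF can land below the best single learner, because
  averaging same-direction biases cannot beat the least-biased member.
* **hard** — the bias learners with jitter 6 px, miss 0.25, 1 FP/image.

What the generator does **not** emulate: correlated misses across
models (misses are independent), confidence–quality correlation within
a model, duplicate detections of one object by one model, and any
appearance variability — so passing tests demonstrate the mechanics and
the bias-correction property, not performance on real colonoscopy data.

## Numerical choices and limitations

* Coordinates are continuous corner coordinates, origin top-left; width
  is `x_max − x_min` exactly. COCO `[x, y, w, h]` records are converted
  with `x_max = x + w` on read.
* Zero-area annotations and out-of-range scores are rejected at load
  time with logged counts; degenerate boxes after clipping are dropped.
* "Available" training matches require IoU strictly greater than
  `min_iou` (default 0); a stricter cutoff is exposed because a
  near-zero-overlap match is a poor regression target.
* OLS standard errors come from the classical covariance
  `s²(AᵀA)⁻¹` and are reported as NaN when the design is singular.
* The cross-validation partition is a seeded permutation dealt
  round-robin into folds: image-disjoint, exhaustive, near-equal sizes.
* Problem sizes throughout the test-suite (200–500 images, 3 learners,
  5 seeds/folds) are chosen so the full synthetic study re-runs in about
  a minute on one CPU while keeping binomial/OLS standard errors small
  enough for the stated 3-SE and ≥4-of-5 assertions.
* Inference-time benchmarking, rotated boxes, segmentation masks and
  learned per-model fusion weights are out of scope.
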