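# Methods

## Problem setting

Authentication of powdered medicinal herbs by microscopy reduces to a small-
object detection task: find and classify the diagnostic "feature cells"
(fibers, stone cells, cork cells, vessels, oil cells, starch granules) in an
RGB micrograph. Real corpora of such slides are severely imbalanced — a few
cell types dominate while others appear in only a dozen images — and the
cells are small, unevenly scattered, often truncated by the field of view,
and blurred by focus and grinding damage. This package implements a complete
detection stack for that setting and exercises it end to end on synthetic
slides, because no public corpus of annotated herb micrographs exists.

## Synthetic slides

`chmmi.synthetic` renders textured, rotated ellipses on a noisy pale
background. Each class has a deterministic style (hue, elongation, texture
frequency, wall darkness); odd-numbered classes are elongated (fiber/vessel
morphology, aspect 3–5), even-numbered ones rounded. A cell drawn with the
`edge_truncation_prob` flag is deliberately placed across the frame border.
Each visible cell's label is the tight bounding box of its rendered pixel
mask, so labels are exact by construction; the whole frame may receive a
Gaussian blur (`blur_sigma` range, pixels). Generation is a pure function of
`(seed, image_index)` with per-image streams `seed + index`, making datasets
reproducible and order-independent.

The default 9-class weight vector is the normalized per-class box-count
profile of a two-herb annotation corpus (9080, 1726, 644, 353, 171, 580,
257, 13, 16 boxes; 12,840 boxes over 11,060 images in total), so the default
generator reproduces that corpus's imbalance shape.

What the generator does *not* emulate: real stain variability, optics,
overlapping cell clusters, and debris. Tests passing on these slides
demonstrate the correctness of the pipeline's mechanics and the *relative*
value of augmentation and attention under imbalance; they do not predict
absolute accuracy on real micrographs.

## Cut-and-recombine augmentation

`chmmi.augment` cuts two slides vertically at `floor(W/2)` into left/right
halves and stitches the four mixed-source ordered recombinations
(aL,bR), (bL,aR), (aR,bL), (bR,aL) — the unique enumeration that yields four
outputs, all differing from both sources. Boxes crossing the cut are clipped
to each half and kept when at least `clip_keep_fraction` (default 0.2) of
their area survives; partially visible cells are a natural feature of
micrographs, so clipping rather than dropping is deliberate. Mirror,
translation and 90-degree rotations complete the repertoire; rotation is
restricted to quarter turns so axis-aligned boxes remap exactly.

The balancing driver measures class frequency in *box* counts (detection
training consumes boxes, not images), repeatedly pairs slides that contain
the most deficient class, keeps only recombinations that carry that class,
and appends products until every class holds at least `balance_ratio`
(default 0.5) of the majority count or a budget is exhausted (a warning, not
an error). Each product records its two source slides so cross-validation
can keep augmented images strictly inside their sources' folds.

## Channel attention

Two gates recalibrate feature-map channels:

* **Squeeze-excitation** (shallow gate): global average pooling gives a
  channel statistic `z`; `omega = sigmoid(W2 relu(W1 z))` with a bias-free
  bottleneck of reduction rate `r = 16` (hidden width floors to 1 for narrow
  maps); the map is rescaled channel-wise by `omega`.
* **Efficient channel attention** (deep gate): the bottleneck is replaced by
  a single bias-free 1-D convolution across `z` with adaptive kernel size
  `k = ||log2(C)/2 + 1/2||_odd` — the odd integer nearest the expression,
  ties and even values resolved upward (C = 2, 16, 256 give k = 1, 3, 5).

Both are pure channel-wise transforms: shape preserving, output bounded by
the input (weights lie in (0,1)), and equivariant under any spatial
permutation. They consume the already-convolved feature map; the surrounding
block owns its convolution.

## Detector

A YOLOv5-style stack built on a small numpy autodiff engine written for this
package (reverse-mode tape; im2col convolution, batch normalization, SiLU,
stride-1 max pooling, nearest upsampling, 1-D channel convolution): CBS
(conv-BN-SiLU) and CSP `C3` stages stride the input down to 1/32 with
squeeze-excitation after the two shallow stages and SPPF at the deepest;
an FPN top-down then PAN bottom-up neck fuses strides 8/16/32 by channel
concatenation; each fused output passes the efficient-channel-attention gate
and a 1x1 head emitting 3 anchors x (5 + n_classes) channels per cell.
Default widths (8, 16, 24, 32, 48) are a deliberately narrow CPU-scale plan;
anchors default to 9-way k-means over the training boxes, sorted by area and
assigned three per scale (small to P3/8, large to P5/32). Objectness biases
start at -4 so the dense no-object grid does not swamp early training.

Decoding: `x = (col + sigmoid(t_x)) / S` (cell-relative), `w = (2
sigmoid(t_w))^2 * anchor_w / W` (anchor-scaled, exponential-free, capped at
4x the anchor).

## Loss

Three summed components over responsible anchor-cells (a ground-truth box is
assigned to the cell containing its center at every scale whose anchor
passes the size-ratio test `max(w/wa, wa/w, h/ha, ha/h) < 4`, with a
best-ratio fallback guaranteeing at least one cell):

* box term: plain squared differences of the decoded x, y, w, h against the
  target (a square-root w/h variant and a 1-CIoU term are selectable);
* class term: squared error of per-class sigmoid probabilities against
  one-hot;
* confidence term: squared error of objectness against a target equal to
  the IoU between the decoded predicted box and its ground truth
  (a constant in the gradient, the YOLO-family convention), with
  `lambda_noobj = 0.5` discounting empty cells.

Library defaults weight the terms (alpha, beta, gamma) = (0.05, 0.5, 1.0).
The CPU-scale benchmark instead trains with (5, 1, 1): with the box term
expressed in squared *normalized* coordinates its raw magnitude is two to
three orders below the confidence term, and the larger alpha restores
comparable gradient pressure on localization. Batch losses are sums over
images; the trainer divides gradients by the batch size before the Adam
step and decays the learning rate by a half-cosine to 10% of its base value.

## Evaluation

Greedy class-wise NMS (score-descending, ties broken by box coordinates so
the result is input-order independent), greedy highest-score-first
one-to-one matching, all-point interpolated AP per class for mAP@.5 and
101-point AP averaged over IoU 0.50:0.05:0.95 for mAP@.5:.95. Conventions:
precision 0/0 -> 0, recall with no ground truth -> 1, classes without ground
truth are excluded from AP means, a zero MCC denominator -> 0.

Detection has no native true negatives, so MCC and the ROC false-positive
rate use a detection-adapted TN: the decision space is the finite set of
anchor-cells over all scales and images, and TN counts cells neither
responsible for a ground-truth box nor firing above threshold. Counts are
micro-averaged over classes. The ROC sweeps score thresholds 0.1–1.0 in 0.1
steps; AUC is trapezoidal with (0,0) and (1,1) appended, and a detector that
never fires is reported with a degeneracy flag.

## Protocol

8:2 train/test split stratified by each image's majority class (plain random
below 5 images, with a warning), five-fold cross-validation producing models
M1–M5, per-model prediction on the held-out test set, and box-cluster
majority voting: detections are clustered greedily by descending score with
cluster IoU >= 0.5, each model contributes at most one member per cluster,
clusters with fewer than `min_votes` (default 3 of 5) distinct models are
dropped, and survivors are emitted with the majority class (ties broken by
summed score), mean box and mean score. With one model and `min_votes = 1`
the rule is the identity, so it reduces to label voting when each model
emits one box. Augmentation runs on the training split only, and an
augmented image enters a fold's training set only when both of its source
slides lie outside that fold's validation portion.

## The CPU-scale benchmark

`chmmi.benchmark.benchmark_config` freezes the end-to-end study conditions:
120 slides of 128x128 px, two classes (rounded majority, elongated fiber-like
minority, 70/30 box mix, blur up to 0.8 px, 15% edge truncation), 8:2 split,
balancing to ratio 0.5 with a 60-image budget, five folds x 14 epochs of
batch-8 Adam at 0.01, 3-of-5 voting. These sizes keep one replicate (full
method plus bare-detector control) around four minutes on a single CPU core.
The elongated minority class is the honest hard case: thin rotated cells
have low IoU tolerance, and it is where balancing and attention visibly earn
their keep.

## Known limitations

* The pure-numpy network is small; absolute mAP on the benchmark is far
  below what a GPU-scale model reaches on real data, by design.
* Anchor-cell TN makes MCC/AUC comparable across runs of this package but
  not directly against detectors with a different decision-space definition.
* Free-angle rotation augmentation is excluded (axis-aligned boxes would
  lose tightness); photometric augmentation is out of scope.
* The balancing driver cannot amplify a class with zero source boxes; it
  warns instead.
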