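# Methods

This note documents the models and procedures implemented in `lsnet`,
the conventions and defaults they use, the design choices made where the
published description leaves the design open, and what the synthetic
test-bed does and does not establish.

## The detection problem and the architecture

The target regime is vertical-view UAV imagery of grazing livestock at
4–7 cm ground resolution: three classes (sheep, cattle, horses) whose
annotated boxes average roughly 20×21, 36×38 and 37×40 px, with most
sheep boxes between 10 and 20 px. Survey frames are 7952×5304 px and are
processed as 1024 px patches with 512 px overlap.

The detector is an anchor-based one-stage network derived from the
YOLOv7 base model. Three modifications adapt it to very small targets:

1. **A stride-4 prediction head (P2).** The top-down neck path is
   extended one level further, to the stride-4 backbone feature, with
   the same up-sample/concat/ELAN-W pattern at halved channel widths,
   and the bottom-up path is extended correspondingly. A 640-px input is
   therefore detected on a 160×160 grid, fine enough that a 15-px sheep
   spans several cells.
2. **Removal of the stride-32 prediction head (P5).** The prediction
   units at stride 32 — the final bottom-up aggregation stage, its REP
   conv and its detect conv — are removed. The backbone's stride-32
   stage and the pyramid pooling on top of it are *kept*: they still
   feed the top-down path with high-level context. This reading is
   fixed by the published ablation arithmetic (see "Parameter
   accounting" below); removing the backbone stage as well would change
   the counts by several million parameters.
3. **LKASPP.** The SPPCSPC pyramid-pooling block is rebuilt: the three
   parallel max pools (kernels 5/9/13) become three *sequential* 7×7
   stride-1 pools, whose outputs (effective kernels 7, 13, 19) are
   concatenated with the unpooled path exactly as before; and the
   post-fusion 3×3 conv is replaced by a multi-scale large-kernel
   attention (MLKA) gate. Each of three attention branches is a
   depth-wise 5×5 conv, a depth-wise dilated 7×7 conv (dilations 2, 3,
   4 per branch), and a point-wise 1×1 conv; a point-wise conv
   aggregates the three branch outputs into a full-channel attention
   map that multiplies the fused features. Branch convs carry biases
   and no batch norm, as in standard large-kernel-attention designs.
   The block's output (512 channels, same spatial size) matches
   SPPCSPC's, so the neck is unchanged.

Blocks follow the YOLOv7 base channel plan and repeat counts (CBS =
conv + batch norm + SiLU; ELAN with four 3×3 convs at full mid-width in
the backbone, ELAN-W with four at half mid-width in the neck; MP =
max-pool+1×1 alongside 1×1+3×3-stride-2). REP head convs are modelled in
their training form (parallel 3×3 and 1×1 branches, summed before the
activation) by default; the fused deploy form is available via
`ModelConfig.rep_mode`.

The whole network is described as a flat graph (a list of nodes naming
their inputs); one description drives instantiation, the forward pass,
parameter counting and static FLOP profiling, which makes the counts
pure functions of the configuration by construction.

## Parameter and FLOP accounting

Parameter counts include conv weights, biases where present, and batch
norm scale/shift (running statistics are buffers, not parameters). FLOPs
are 2 × multiply–accumulates over convolution layers only, batch norm
folded; pooling, up-sampling, activations and the attention
multiplication are not counted. `n/(n−1)`-style corrections aside, these
are the conventions of the common detector profiling tools.

The published ablation table's parameter column is reproduced *exactly*
(to the printed 10⁻³ M) by the stock summary configuration: an 80-class
head layout with training-form REP convs. Under that convention this
implementation counts 37,620,125 (baseline), 26,337,950 (−P5),
26,919,709 (−P5+P2) and 38,201,884 (+P2, four heads) — each matching
its printed value — which is what identifies both the wiring of the
ablation variants and the counting convention. Only the LKASPP-bearing
rows depend on internals the source never specifies; the MLKA design
above gives 26,251,037 against a printed 26.247 M, a residual of
0.004 M (0.016%) attributable to those unstated internals. The 3-class
task configuration is the package default everywhere else; it counts
about 1% lower (e.g. 26,043,368 for the full model) because only the
1×1 detect convs change with the class count. FLOPs under the stated
convention come out ~1–1.5% below the printed column (111.67 vs
113.385 GFLOPs for the full model at 640); the deltas *between* variants
match almost exactly, so the residual is a counter-convention offset
(the original tool evidently counts some non-conv ops), not a structural
difference. `scripts/acceptance.py` reports the summary-convention
numbers.

## The Wise-IoU v3 loss

For an aligned pair of boxes (centres b, b_gt; enclosing box extents
c_w, c_h; centre distance ρ):

- `L_IoU = 1 − IoU`
- `R_WIoU = exp(ρ² / (c_w² + c_h²))`, the denominator detached
- `L_WIoUv1 = R_WIoU · L_IoU`
- outlier degree `β = L_IoU* / mean(L_IoU)` — the pair's detached IoU
  loss over an exponential running mean of IoU losses (momentum 0.99,
  updated once per training step from the batch mean)
- focusing factor `r(β) = (β/δ) · α^(δ−β)` with defaults α = 1.9,
  δ = 3: r(0) = 0, r(δ) = 1 exactly, unique maximum at β = 1/ln α ≈
  1.558, r → 0 as β → ∞
- `L_WIoUv3 = r · L_WIoUv1`

Orientation of β: the formulation is used here with β = L_IoU/mean, so
that a *smaller* β means a *higher-quality* box — the orientation under
which the quality narrative and the focusing behaviour are consistent; a
config switch (`FocusingConfig.beta_orientation`) provides the
reciprocal. Three quantities are excluded from gradients by
construction: the attention normaliser, β, and the running mean; the
α-weight of the CIoU aspect term is likewise detached, following the
reference implementations. During the first 500 steps (configurable) r
is pinned to 1, since β against an unsettled mean is noise. Denominators
are floored at 10⁻⁷, and IoU is clamped to [0, 1] against float
round-off in corner reconstruction. CIoU, WIoU v1 and (smoke-tested)
WIoU v2 are available through the same API; all accept plain arrays or
autodiff tensors.

## Anchors

Anchors are estimated by k-means++ seeding plus Lloyd iteration over
training-set (w, h) pairs, under the 1 − IoU distance between a box and
a centroid placed at a common centre — the quantity the assignment rule
actually cares about (squared Euclidean is available). Iteration stops
when assignments freeze or at 300 rounds; the seed drives only the
k-means++ sampling. The nine centroids are sorted by area and grouped
3/3/3, smallest to the stride-4 head. Fractional anchors are kept as
floats. Whether the reference anchors were clustered in original or
640-rescaled pixel space is unstated; this implementation clusters in
rescaled space, which is the space the printed anchors are consistent
with.

## Tiling

Tile origins lie at multiples of `tile − overlap` with the final origin
clamped to the frame edge (content is always real pixels); frames
smaller than the tile are padded bottom-right with gray (114, 114, 114).
Coordinates are 0-based with half-open tiles. Annotation clipping keeps
a box in a tile when its visible area fraction is ≥ `min_visibility`
(default 0.3) and both clipped sides are ≥ 2 px. Merging shifts
detections to frame coordinates and applies class-wise NMS (default IoU
0.5), keeping the highest-confidence copy. With 50% overlap every
interior point lies in ≥ 2 tiles per axis, which is what makes the
clip→merge round trip lossless for objects smaller than the overlap.

## Training

Defaults follow the published protocol: SGD, momentum 0.937, weight
decay 4×10⁻⁵ (conv weights only), cosine learning rate
`lr(e) = lr_min + (lr_init − lr_min)(1 + cos(πe/E))/2` from 0.01 to
10⁻⁴, 300 epochs, batch normalisation with momentum 0.03. The loss is
`0.05·box + 1.0·obj + 0.5·cls` (BCE for objectness and class), with the
box term selectable among CIoU / WIoU v1 / WIoU v3.

Target assignment uses the mainstream size-ratio gate (anchor eligible
when max(wh/anchor, anchor/wh) < 4) over the centre cell plus its two
nearest neighbours — a deliberate simplification of the dynamic
assignment used by modern YOLO trainers, documented as a fidelity gap.
Two alternatives exist as config switches because they matter at small
scale: `assign_mode="best"` (single best-IoU anchor per target) and
`balanced_obj` with `obj_focal_gamma` (positive and negative objectness
cells averaged separately, negatives focally weighted by σ^γ). The
objectness target at a matched cell is the detached IoU of the decoded
prediction (`obj_target="one"` gives hard positives instead).
Augmentation is horizontal/vertical flips only — both are valid for
vertical aerial views; mosaic is out of scope. Step-level linear warm-up
is available and off by default, so `lr_schedule` is exactly the cosine
law.

Two numerical choices born of the small-batch regime: batch-norm running
variance stores the biased batch variance, and after training (and
before any mAP evaluation) running statistics are recomputed exactly
over the training set in one pass (precise-BN). Without this,
evaluation-mode normalisation drifts from training-mode normalisation,
and the multiplicative attention gate in LKASPP amplifies that drift
layer by layer into unusable predictions after short runs. With
full-dataset batches the recomputed statistics coincide exactly with
what training used.

Decoding is the standard sigmoid parameterisation — centre
`(2σ(t_xy) − 0.5 + cell)·stride`, size `(2σ(t_wh))²·anchor`, score
`σ(obj)·σ(cls)` — with per-class NMS; the score threshold is strict
(`>`), so an all-zero head (score exactly 0.25) yields no detections at
the 0.25 default.

## Evaluation

VOC protocol: greedy matching in descending confidence, one detection
per ground-truth box, boundary-inclusive IoU threshold (default 0.5),
ties broken by higher IoU. AP integrates the precision envelope over all
recall points (the VOC-2010/COCO convention; 11-point interpolation is
available, and the two typically differ by a few points on short
rankings — the source does not state which it used). mAP is the
unweighted class mean; F1 is reported at the confidence maximising it.
Classes without ground truth yield NaN AP with a warning and are
excluded from mAP. "Difficult" flags are not supported.

## The synthetic test-bed

`lsnet.synthetic` renders grass-textured scenes (multi-scale smoothed
value noise) with animals as anti-aliased rotated ellipses plus a soft
shadow and a mild highlight. Box side lengths are truncated normals
matching the survey statistics — means 20.04/20.89 (sheep), 35.71/37.67
(cattle), 37.16/39.71 (horse) px, truncated to the survey's observed
min/max ranges; the spreads (σ = 5 px sheep, 9 px cattle/horse) are
chosen so most sheep boxes fall in the 10–20 px band. The reference
statistics give no σ, so these are this package's choice. The default
scene density (17 sheep : 5 cattle : 1 horse per 1024-px patch) mirrors
the survey's 76:21:3 class mix at its mean density of ~22 animals per
patch. Orientation is sampled within the range for which a rotated
ellipse with the drawn support box exists, and the stored ground truth
is the rendered body's pixel-support box (shadow excluded), so labels
are exact by construction. Placement is herd-clustered (Gaussian spread
around herd centres) with a pairwise separation floor; an overcrowded
configuration raises after bounded retries rather than silently
overlapping. Dataset trees follow the nested 9:1, 9:1
train/val/test partition (81/9/10).

What passing tests on this test-bed establishes: the geometry, loss,
assignment, decoding, NMS, tiling and metric code paths are correct, and
the training loop can drive a model to memorise known truth. What it
does not establish: accuracy on real imagery — the blobs lack pose
variation, occlusion, confusable background objects (rocks, shrubs,
buildings), lighting and atmospheric effects, and inter-class ambiguity
is far below that of real cattle vs horses.

## Scale of the shipped experiments

The full-size detector is exercised for structure (a real 640-px forward
pass, parameter/FLOP accounting); learning experiments run at reduced
scale chosen for a single CPU core: the memorisation check trains a
width-0.25 model on eight 160-px scenes (4 sheep/2 cattle/2 horses
each) for 400 full-batch steps with `assign_mode="best"`,
`balanced_obj=True`, `obj_focal_gamma=2`, `lambda_box=1.0`, reaching
train-set mAP@0.5 ≥ 0.99 in about five minutes. The stronger box weight
and the balanced/focal objectness are what make the 3,000-step-scale
run converge; at the published 300-epoch scale the conventional weights
are the defaults. Reported quantities from the published study that
require the restricted survey data and GPU-scale training (e.g. the
93.33% mAP headline) are out of scope by design; the package
reproduces the architecture's structural statistics and validates the
method's components against exact oracles instead.

## Known limitations

- No simOTA-style dynamic assignment, no mosaic/HSV augmentation, no
  EMA of weights — the training recipe is a documented simplification.
- The numpy backend is single-threaded BLAS-bound; full-width 640-px
  training is out of reach (a full forward pass takes ~6 s), which is
  why learning experiments are width-reduced.
- REP training-form convs are supported, but re-parameterised fusion of
  trained weights into deploy form is not implemented (deploy-form
  models train directly instead).
- Checkpoints store arrays keyed by module path; architectural changes
  invalidate them.
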