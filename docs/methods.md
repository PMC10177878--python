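# Methods

## Problem and model

The package segments three instance classes in sagittal T2-weighted
MRI-like images: `uterine_wall` (id 1), `uterine_cavity` (id 2) and
`myoma` (id 3). The detector is a two-stage pipeline: a multi-resolution
backbone produces a feature pyramid, a region-proposal network (RPN)
scores data-fitted anchors, and ROI heads predict class, box and a
point-refined mask per instance.

### Backbone

The stem downsamples the input to 1/4 resolution with two stride-2 3×3
convolutions. Parallel branches then run at strides 4/8/16 (desk profile;
4/8/16/32 at full scale). Each stage applies a two-convolution block per
branch followed by a full cross-resolution exchange unit (strided 3×3
convolutions downward, 1×1 convolution + bilinear upsampling upward,
summation, ReLU). After the final stage all branches are upsampled to
stride 4, concatenated and fused by a 1×1 convolution; stepwise 2×2
average pooling yields P3/P4/P5 (strides 8/16/32). The number of exchange
units equals the number of stages; this placement — like the insertion
points for attention — is a design choice, fixed here once.

The second convolution of each branch's final block is deformable:
sampling positions are displaced by offsets predicted from the same input
by a zero-initialized convolution, so training starts exactly at the
regular-convolution limit and the offset field grows as needed. Fractional
positions use bilinear interpolation; samples outside the map contribute
zero, matching zero padding.

CBAM attention is applied once per pyramid level after fusion: channel
gating first (shared two-layer MLP over global average- and max-pooled
vectors, added, sigmoid; reduction ratio 4 desk / 16 full), then spatial
gating (7×7 convolution over the stacked channel-wise average and max
maps, sigmoid).

All convolution stacks use group normalization (8 channel groups, or fewer
when the width demands it). The networks here train from random
initialization — there is no pretraining corpus for this modality — and
without normalization the shared trunk conditions so poorly that the ROI
heads chase a moving feature distribution instead of converging.
Prediction layers (RPN objectness/deltas, class scores, box deltas, mask
logits) are initialized with small weights (σ = 0.01 or 0.001) so early
gradients do not swamp the trunk.

### Anchors

Anchor fitting collects all training-box (width, height) pairs and runs
k-means under D = 1 − IoU with box centers aligned. Centroid update is the
element-wise median (robust, standard for IoU k-means); assignment ties
break toward the lowest cluster index. Lloyd iteration is a local search,
so initialization matters: problems with at most 5000 distinct k-subsets
are solved by running Lloyd from **every** k-subset of distinct boxes
(deterministic, seed-free); larger problems use k-means++-style seeding
under D with 10 restarts, keeping the best average IoU. k = 9 by default,
reduced to the largest feasible multiple of 3 on very small datasets. The
nine centroids, sorted by area, are assigned in triplets to P3/P4/P5.
Anchors are used directly as (w, h) pairs, three per feature-map cell,
centers at stride·(i + 0.5).

### Detection heads

RPN: one shared 3×3 convolution + ReLU, then 1×1 heads for objectness and
box deltas. Anchor labels use IoU thresholds 0.7/0.3 with force-matching
so every ground-truth box owns at least one positive anchor; 64 anchors
(256 full-scale) are sampled per image at up to 1:1 positive:negative.
Proposals: decode, clip, drop degenerate boxes, keep the top 600 by score
(2000 full), NMS at 0.7, keep 200 train / 100 test (1000/300 full).

ROI heads: proposals are routed to a pyramid level by
`level = floor(3 + log2(sqrt(area)/224))` clamped to [3, 5] — at desk
scale essentially everything lands on P3, which is intended: the desk
image is 1/4 the linear size of the clinical frame. ROIAlign pools 7×7
(box head) with 2×2 bilinear samples per bin, no coordinate quantization.
The box head is two fully connected layers (128 desk / 1024 full) with a
(background + 3)-way softmax and per-class box deltas; regression targets
are normalized by (0.1, 0.1, 0.2, 0.2). Ground-truth boxes are appended to
the proposal set during training, ROIs are sampled 32 per image at half
foreground.

### Mask branch

Mask features are pooled at 14×14 (28×28 full) from the fused stride-4
map — the finest representation available — rather than from the P3–P5
levels, because the thin cavity and the wall's inner boundary are
sub-cell structures at stride 8 and coarser. The coarse head (two 3×3
convolutions, one stride-2 convolution, 1×1 output) predicts a 7×7
per-class logit grid (14×14 full).

During training every ground-truth box is supervised as a mask ROI on
every pass, topped up with sampled foreground proposals (12 ROIs total
desk / 32 full). Anchoring mask supervision at the ground-truth boxes
keeps the target grids consistent between passes; the added jittered
proposals expose the head to the imperfect boxes it will receive at
inference. Coarse targets are the ground-truth mask bilinearly sampled at
cell centers and thresholded at 0.5.

Point refinement: at training, kN uniform candidate points are drawn per
mask ROI (k = 3), the β·N most uncertain (|p − 0.5| smallest, β = 0.75)
are kept and (1−β)·N fresh uniform points added (N = 49 desk / 196 full).
Per-point features concatenate a bilinear sample of the stride-4 map with
the ROI's coarse logits at that point; the point head is an MLP with 3
hidden layers (64 desk / 256 full channels), the coarse logits re-appended
to every hidden layer's input. At inference the class probability grid is
repeatedly 2× bilinearly upsampled to 56² (112² full); after each step the
64 (784 full) grid points nearest p = 0.5 are re-predicted, ties breaking
in row-major order. Unselected points are bit-identical to plain bilinear
upsampling. Masks are binarized at 0.5 and pasted into the image frame by
bilinear resampling of the probability grid at pixel centers.

### Loss and optimization

`L = λ1·Lcls + λ2·Lbbox + λ3·Lmask`, λ = (1, 1.2, 1). `Lcls` comprises
RPN objectness BCE and ROI cross entropy; `Lbbox` comprises RPN and ROI
smooth-L1 terms (positives only, normalized by the positive count);
`Lmask` is the mean coarse-grid BCE plus the mean point BCE, penalizing
only the ground-truth class's channel. Inverse-frequency class weights
`w_c = T/(C·n_c)` enter the ROI cross entropy only; the mask loss is
already class-gated and the RPN is class-agnostic.

SGD with momentum 0.9 and L2 weight decay 1e-4 throughout. Full profile:
lr 0.001, 60 epochs, batch 4, 512² inputs. Desk profile: lr 0.02, 10
epochs, batch 2, 128² inputs — the larger step size is required because
the desk network trains from scratch; gradients are clipped at global norm
10 for stability in either profile. Gradients are accumulated over
`batch_size` single-image passes per optimizer step. Augmentation
(probability 0.5 each): horizontal/vertical flips, rotation uniform in
±15°, central crop with scale in [0.8, 1]; masks and boxes transform with
the image and emptied instances are dropped.

## Synthetic phantoms

Each phantom contains: an elliptical wall annulus (outer semi-axes
0.20–0.30 / 0.16–0.24 of the image side, inner scale 0.55–0.68, random
rotation ±0.5 rad); one thin bright cavity ellipse inside the annulus hole
(semi-minor = cavity_thickness_frac/2 × inner semi-minor, default
thickness fraction 0.5 — at clinical resolution this corresponds to a
roughly 10–12 mm endometrial stripe); 0–4 dark myomas with log-uniform
radii (0.02–0.17 of the side, giving boxes mostly under 260 px at the 512
scale with aspect ratios mostly under 2 and mode 1), placed intramurally,
submucosally or subserosally with equal probability; bright distractor
discs and a dark vertical column (spine analog) outside the uterus,
carrying no annotation; a multiplicative bias field exp(random quadratic)
with peak log-amplitude 0.15; additive Gaussian noise σ = 0.03. Intensity
ordering is enforced: cavity (0.90) > wall (0.52) > background (0.40) >
myoma (0.25) — wall/background contrast is deliberately low. The cavity is
painted last: on T2 imaging the fluid line remains visible where a
submucosal myoma indents it.

What the phantoms do **not** model: Rician noise statistics, partial-volume
and motion artifacts, anatomical variation beyond ellipse compositions,
multi-organ context (bladder, bowel loops are reduced to bright discs),
and 3-D continuity across slices. Passing the test suite therefore
demonstrates that the pipeline's machinery is correct and that the design
components behave as intended on data with the right coarse statistics; it
does not certify clinical performance.

Generation is deterministic: image `index` under seed `s` uses the
`default_rng([s, index])` stream, so datasets are byte-identical across
reruns, machines and split layouts.

## Evaluation

COCO protocol: greedy per-image matching in descending confidence at each
of the 10 IoU thresholds 0.50:0.05:0.95, at most 100 detections per image;
ground truths outside an area range ([0, 32²), [32², 96²), [96², ∞) for
APs/APm/APl, area = mask pixel count) are ignored, as are detections
matched to them and unmatched detections outside the range; 101-point
interpolated precision with the running-max envelope; category-mean AP.
Mask IoU is computed on the full-resolution binary masks directly. The
test suite cross-checks this implementation against an independently
written loop-based reference on randomized result sets (agreement ≤ 1e-6).
The confusion matrix matches detections to ground truths class-agnostically
at mask IoU 0.5 (a design default; the threshold is not prescribed) and
row-normalizes; unclaimed ground truths count toward a background column.

## Scaled-down test conditions

CPU-sized runs define the test surface: the desk profile at 128² with
backbone widths (8, 16, 32) and 2 stages. The overfit check trains on 2
phantoms for 200 optimizer iterations (batch 2) and requires training mask
AP50 ≥ 0.99; the generalization check uses a 90-phantom 80/10/10 split for
10 epochs and requires validation mask AP50 ≥ 0.5 plus validation mask AP
at or above an identically trained baseline with deformable convolution,
attention, anchor fitting and point refinement all disabled. Problem sizes
(image counts, epochs, network widths) were chosen so a full suite run
completes in well under half an hour on a single core.

## Numerical choices and degenerate inputs

- Float64 arithmetic throughout the autodiff core; the
  deformable-vs-regular convolution identity holds to ~1e-15.
- Bilinear sampling uses the half-pixel convention (pixel centers at
  i + 0.5); out-of-image samples contribute zero in feature space, while
  probability-grid sampling clamps at borders.
- Constant images: histogram equalization returns them unchanged, Z-score
  returns zeros with a warning.
- Masks are stored as a single polygon only when the traced contour
  rasterizes back to the identical pixel mask (typical for convex blobs);
  anything else — annuli in particular — falls back to uncompressed
  column-major RLE. Round-trips are pixel-exact by construction.
- k-means ties (assignment) break toward the lowest cluster index;
  centroids are reported area-sorted.
- NMS ties (equal scores) keep the lower index; all score sorts are
  stable.
- Empty proposal sets, images without foreground ROIs, and classes absent
  from a dataset are all handled (zero losses / absent AP entries rather
  than errors).
- A non-finite training loss aborts with the per-branch values in the
  message.

## Known limitations

- The mask output resolution (56²/112²) bounds achievable boundary
  accuracy for very large instances.
- The desk profile routes almost all ROIs to P3; the level-routing rule
  only differentiates at clinical scale.
- Per-category AP on the rare thin cavity and on very small myomas is
  noticeably lower than for the wall — the same ordering of difficulty
  reported for clinical data, and at desk scale small myomas are only a
  few pixels wide.
- The full-scale profile replicates the published recipe structurally but
  training it is a multi-hour CPU job; only the desk profile is exercised
  by the tests.
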