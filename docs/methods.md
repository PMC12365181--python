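# Methods

This note documents the statistics, the model and the procedures the
package implements, the choices made where the design was genuinely open,
and what the synthetic experiments do and do not demonstrate.

## Macroscopic correlation (MC)

Each annotated bounding box is treated as a 4-vector `B = [x, y, w, h]`.
For an image with `N >= 2` boxes,

    MC = sum_a sum_{b != a} |PCC(B_a, B_b)| / (N (N - 1)),

the mean absolute Pearson correlation over ordered box pairs, so
`MC ∈ [0, 1]`. High MC means the boxes in an image "move together" in
position and size — the regime of anatomy-rich laparoscopic frames, where
gallbladder, cystic structures and working tools form tight spatial
arrangements. Dataset-level reports bin per-image values into the
conventional correlation-strength bands low `[0, 0.3)`, moderate
`[0.3, 0.5)`, strong `[0.5, 1.0]`; the band edges overlap in their usual
verbal statement, so this package declares half-open-left intervals and
tests them.

Numerical choices:

* A box vector whose four components are all equal has zero variance and an
  undefined PCC. Such pairs are dropped from numerator *and* denominator;
  the plain `N(N-1)` denominator is recovered exactly whenever no pair is
  degenerate. Images with `N < 2` or no defined pair report `nan`, counted
  separately — never silently coerced to 0, because single-box images are
  common in tool-only datasets and a 0 would masquerade as "low
  correlation".
* MC is convention-dependent (corner vs center coordinates change the x/y
  components). The default is corner-absolute pixels — the boxes exactly as
  stored in COCO annotations; the CLI exposes `--convention` for the other
  readings. PCC is affine-invariant per common map, so absolute vs
  normalized coordinates give the same value as long as both axes share one
  scale; anisotropic image sizes make the conventions genuinely differ.
* Interpreting the mean |PCC| of 4-component vectors needs a baseline:
  *independent* random boxes already average around 0.55-0.6 because the
  four components share a common magnitude pattern. The band structure is
  therefore most informative as a contrast between datasets, which is how
  the package uses it.

## Relation encoding

For an ordered pair of center-convention boxes the geometry features are

    e(B_a, B_b) = [ log(|xa-xb|/wa + 1), log(|ya-yb|/ha + 1),
                    log(wa/wb), log(ha/hb) ],

invariant under uniform rescaling of all coordinates, zero for identical
boxes. Each scalar feature is expanded by the standard sinusoidal encoding
with scaled argument, `sin/cos(s·e / T^(2k/d))` for `k = 0..d/2-1`, with
defaults `T = 10000`, `d = 16`, `s = 100` (so each pair yields a
64-dimensional embedding). A learned linear map `W` (4d → M heads) plus
offset `A`, clamped elementwise at `eps = 1e-6`, produces one positive
scalar per attention head and ordered pair:

    relation(B, B') = max(eps, W · Embed(e) + A),  shape N × N × M.

The clamp keeps every bias entry positive so its gradient path never dies.
The bias is added directly to the pre-softmax self-attention logits
(`softmax(relation + QKᵀ/√d_model)`); a `log_domain`-style transformation
was considered and rejected in favour of the additive form as written.
Because the softmax is shift-invariant, a row-constant bias provably
reduces relation-biased attention to plain attention — this identity is the
backbone of the attention test suite.

Open points resolved here: `A` is treated as a learned parameter
(initialized at `eps`, with `W` small-uniform, so the initial bias is
near-neutral and does not drown content attention); relation bias is
applied in decoder self-attention only, since the encoder's own blocks are
described as standard; boxes entering the relation computation are
stop-gradient, so the bias acts as a geometry prior rather than a second
box-regression path (gradients reach `W`, `A` only — verified against
finite differences).

## The mini detector

The full-scale published configuration (256-d embeddings, 900 queries, 1500
hybrid candidates, 6+6 layers, pretrained ResNet/Swin/Focal backbones, five
feature levels) is out of scope for a CPU-bound package; the architecture is
reproduced at desk scale and exposed as `ModelConfig.mini` (64-d, 2+2
layers, 20 matching + 40 hybrid queries, one feature level from a 3-block
strided conv backbone on 64×64 inputs). `ModelConfig.full_scale` carries
the published numbers for reference; it builds, but is not meant to be
trained here.

Design choices that were genuinely open:

* **Two-stage selection.** The first decoder layer needs reference boxes
  for `relation(B_0, B_0)`. Encoder tokens carry class/box heads; the
  top-scoring tokens seed each query stream: query content = learned
  embedding + projection of the selected token, `B_0` = the token's
  predicted box. Proposal boxes are parameterized as offsets from the
  token's own grid cell, and the proposal heads are supervised as an extra
  one-to-one "layer 0" of the matching loss.
* **Box parameterization.** Layer `l+1` refines the running reference in
  logit space, `B = sigmoid(MLP(Q) + logit(ref))`, with the box-head output
  layer zero-initialized so each layer starts as the identity refinement.
  Plain absolute regression (`sigmoid(MLP(Q))`) is available via
  `ModelConfig.box_delta=False`, but at this scale it leaves decoder layers
  unable to improve on the encoder proposals (held-out AP@50 stayed below
  ~12 in the same budget where delta refinement reaches 70+), so
  refinement is the default.
* **Layer composition.** The compact layer formula
  `Q_{l+1} = FFN(Q_l + Attn_cross(Attn_self(Q_l), ...))` is realized as the
  standard transformer decoder layer with pre-norm residual blocks; the
  abbreviated composition is read as naming the information flow, not as
  banning normalization and residuals.
* **Classification.** Per-class sigmoid heads with focal loss
  (γ = 2, α = 0.25); the head width includes a background column (trained
  as the target of unmatched queries, ignored at inference) to honour the
  "n classes + 1 background" output contract. Class logits start at the
  focal prior (−3) to keep early training from being swamped by negatives.
* **Hybrid-to-category assignment.** "K = 6 assigned to each category" is
  realized as ground-truth repetition in one-to-K matching (the tiled-list
  reading of the repeated ground truth), not as a per-category query quota,
  which the source formula does not define.
* **Relation boxes per layer.** The bias of the layer consuming `Q_l` uses
  the two most recent box sets, `relation(B_{l-1}, B_l)`, with
  `relation(B_0, B_0)` at the first layer. Cross-attention is identical for
  both streams; only self-attention differs.

## Matching and loss

The assignment cost is the DETR-family composite
`cost[q, g] = λ_cls (1 − p_q(class_g)) + λ_L1 ‖B_q − B_g‖₁ + λ_giou (1 −
GIoU(B_q, B_g))` with defaults `λ = (2, 5, 2)`; the source specifies
neither components nor weights, so these are config-exposed conventions.
One-to-one matching uses the Hungarian algorithm (via
`scipy.optimize.linear_sum_assignment`, checked against exhaustive
permutation enumeration up to 7×7); one-to-K tiles the ground-truth list K
times before matching, shrinking K with a warning when `K·n_gt` exceeds the
query count. Per-layer loss = focal classification over all queries
(unmatched → background) + L1 + (1 − GIoU) over matched pairs, each box
term normalized by the number of matches; the total is the sum over
decoder layers and both streams. Assignment ties are broken
deterministically (lowest query index).

Training uses Adam with decoupled weight decay (1e-4), lr 1e-3 with a ×0.1
step after epoch 8, batch size 4 — from-scratch values chosen for the mini
scale; the published fine-tuning regime (lr 1e-4, milestone 12, γ 0.1,
16 epochs) is retained as the documented full-scale setting.

## Evaluation

`map_range` implements the COCO protocol: per class and IoU threshold
(0.50:0.05:0.95), predictions sorted by descending score are greedily
matched to the not-yet-matched ground-truth box of highest IoU in the same
image (IoU at the threshold counts, with a 1e-10 guard); AP is the mean of
the right-envelope precision sampled at 101 recall points, scaled to 0-100;
mAP averages per-class AP, excluding classes with no ground truth;
detections are capped at 100 per image. The literal integral of the
interpolated step curve is available as `integration="exact"`. The test
suite cross-checks the vectorized evaluator against an independent,
loop-based transcription of the same protocol on random fixtures (0.1 AP
tolerance) and verifies the duplicate-penalty property that motivates
one-to-one matching: appending a lower-scored duplicate never raises AP.

## Postprocessing

`topk_filter` keeps, per image and category, the k highest-scoring
predictions (k = 1 default; named overrides such as `{tool: 2}` mirror the
two-instrument prior of anatomy-style scenes). Filtering is per image —
dataset-level filtering would be inconsistent with per-frame counting in
the before/after accounting. Ties at the k-th rank keep the earlier record;
kept records preserve input order, making the filter idempotent.
`reduction_report` tabulates ground-truth counts, prediction counts before
and after, the metric change when evaluation results are supplied, and the
percent reduction in prediction counts.

## Synthetic scenes

The generator emulates the two dataset regimes with one coupling knob
`rho ∈ [0, 1]`: each image draws a latent anchor and a shared scale; box
centers are `anchor + (1 − rho)·offset` and box sides
`shared_scale^rho · (mid + (1 − rho)·spread)`, so `rho = 0` gives
independent boxes and `rho = 1` a rigid cluster of near-identical boxes.
Mean dataset MC is monotone in `rho` (tested over seed triplets). Presets:

* `endoscapes-like` — 6 classes, 2-6 boxes per image, `rho = 0.85`
  (strong-band fraction ≈ 0.95);
* `m2cai16-like` — 7 tool classes, 1-2 boxes per image, `rho = 0.1`
  (strong-band fraction ≈ 0.65-0.70, with single-box images reported as
  undefined); the 1-2 multiplicity encodes the qualitative "one or two
  tools per frame" description, no quantitative distribution being
  available;
* `easy` — 3 classes, large flat-colored shapes, used by the trainability
  check.

Rendering is flat-colored ellipses/rectangles/triangles (one color+shape
per category, slight per-instance jitter) on a low-frequency brown-noise
background. This is deliberately learnable, CPU-cheap imagery. What passing
tests show: the architecture, losses and training loop can fit a detection
task end-to-end and the statistics behave as specified. What they do not
show: performance on real laparoscopic video — no occlusion, motion blur,
specularity, deformable tissue, or annotation ambiguity is simulated.

The over-complete prediction generator (jittered copies of true boxes at
high scores plus random boxes at low scores, a fixed number of records per
image) stands in for raw per-query detector output where postprocessing and
evaluation need hundreds of scored boxes per image.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; no global state. Model initialization and
forward passes are bitwise-reproducible under a fixed seed. The bundled
experiments use desk-scale sizes chosen as the package's own defaults: the
trainability check trains the mini detector for 10 epochs on 200 easy
64×64 scenes and evaluates 50 held-out scenes (a ~1-minute CPU run per
seed; held-out AP@50 lands in the 70-85 range, against a pass bar of 50,
for at least 2 of 3 seeds); the reduction experiment filters 100 raw
predictions per image on 50 six-class scenes (~93% reduction). Evaluator
fixtures stay below 10 images so the brute-force oracles remain exact.

## Known limitations

* Single feature level and tiny backbone; no deformable attention, no
  denoising queries, no pretrained weights — relative performance numbers
  from full-scale experiments cannot be reproduced here.
* The VariFocal classification option follows its standard published form
  and is off by default; the source names it only among pre-training
  parameters and gives no formula.
* `float64` throughout: exactness over speed; training beyond desk scale
  is out of scope.
* MC on real datasets requires their annotation files; the package ships
  only the synthetic emulation of the strong-vs-weak contrast.
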