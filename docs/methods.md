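# Methods

This note documents the model and training procedure implemented by
`wildface`, the parameters that matter and why they hold their defaults,
what the synthetic data generator does and does not emulate, and the
numerical and design choices made where the design was genuinely open.

## Task and model

The task is closed-set individual re-identification: every face image shows
one of K known individuals and the model must say which. The recognizer is
a vision transformer (patch embedding, class token, pre-norm attention
blocks, final layer norm) whose class-token feature feeds two heads:

- **classifier**: dropout 0.2 → FC → GELU → dropout 0.3 → FC → GELU →
  dropout 0.24 → linear output. The decreasing dropout rates regularize
  more aggressively at lower abstraction levels.
- **projection**: FC(→512) → GELU → FC(→256) → L2 normalization, producing
  the unit embeddings on which the contrastive loss operates.

The backbone is required to expose, per layer, the full token-to-token
attention matrices with gradient flow — this is what makes the quantitative
interpretability below possible, and is the reason the package ships its own
numpy transformer (`wildface.nn`: a compact tape-based reverse-mode autodiff
engine in float64 plus the ViT built on it) rather than treating the network
as a black box. `tiny_test_backbone()` provides a 17-token, 4-layer instance
on which every code path runs in seconds on one CPU.

## Objective

`L_total = L_focal + α·L_SupCon`.

**Focal loss** (γ = 2.0, per-class balancing factors α_t default 1):
`−α_t (1−p_t)^γ log p_t` averaged over the batch. For soft targets produced
by MixUp/CutMix the loss is the convex combination of per-class terms under
the target weights, which reduces to the standard form for one-hot labels.
Probabilities are clamped at 1e−12 so the loss is always finite. α_t stays
at 1 because imbalance is already handled by weighted sampling; frequency
based factors are available through `LossConfig`.

**Supervised contrastive loss** (τ = 0.07): for each anchor, positives are
the other same-label batch members and the denominator runs over all other
members; the per-anchor average of log-softmax terms is averaged over
anchors that have at least one positive (so batch size does not rescale the
objective). A batch with no positive pairs contributes 0 with a warning.
Similarity is the inner product of already-unit-norm embeddings (asserted).
The contrastive term is skipped on mixed batches by default — soft labels
break the positive-set definition; a configurable alternative assigns each
mixed sample its majority label.

## Adaptive schedules

All schedules are pure functions of `(epoch, latest test accuracy/F1)`;
stage tables are data, not code. Stage intervals are closed on both printed
endpoints, epochs are 0-indexed, and accuracy thresholds use strict `>`
("exceeds") with a closed [0.80, 0.90] band for the cap rule.

| epochs | MixUp/CutMix (α, p) | SupCon weight α |
|---|---|---|
| 0–4 | off | 0.05 |
| 5–9 | 0.3, 0.3 | 0.05 |
| 10–14 | 0.3, 0.3 | 0.08 |
| 15–19 | 0.5, 0.5 | 0.08 |
| 20–29 | 0.5, 0.5 | 0.06 |
| 30–44 | 0.4, 0.4 | 0.03 |
| 45–59 | 0.3, 0.3 | 0.03 |
| ≥60 | 0.2, 0.2 | 0.03 |

Overrides, evaluated per epoch after staging: accuracy > 0.92 sets mixing to
(0.1, 0.1) (never re-enabling it during the opening no-mixing stage);
accuracy > 0.90 forces the SupCon weight to 0.02; accuracy in [0.80, 0.90]
caps it at 0.05.

When a batch is mixed, CutMix and MixUp are chosen 50/50. One λ ~
Beta(α, α) is drawn per batch; MixUp partners come from a uniform batch
permutation (self-pairing allowed). CutMix uses the standard area law: the
rectangle's area fraction is 1−λ with aspect ratio uniform in [0.5, 2],
center uniform, clipped to the image, and λ recomputed from the realized
kept area so the label weights match the pixels exactly.

**Optimizer policy**: AdamW, base learning rate 3e−5, weight decay 1e−4.
Reduce-on-plateau monitors test F1: when the trailing `patience` epochs
(default 5 — unstated in the source recipe, made configurable) bring no
strict improvement over the best before them, the rate halves, floored at
1e−7. The fine-tune gate latches: once test accuracy exceeds 0.90 the rate
is capped at 1e−5 for all later epochs ("switching to fine-tuning mode" is
a mode change, not a per-epoch condition). Early stopping defaults to 15
epochs without F1 improvement; the checkpoint kept is the highest-F1 one.

## Augmentation stack

Operators act on float images in [0, 1]; every random decision comes from an
explicit generator, so pipelines are bit-reproducible. Defaults: resize to
1.1× the input size then random crop; horizontal flip p = 0.5;
shift ≤ 8% / scale ±10% / rotate ±10° with p = 0.5; one of color jitter
(brightness/contrast/saturation ±15%, hue ±5%) or HSV offsets (10/15/10 on
the 8-bit HSV scale) with p = 0.5; independent brightness/contrast ±15% with
p = 0.4; Gaussian noise (variance 5–25 on the 0–255 scale — the scale is a
convention choice recorded here) or blur (kernel 3 or 5) with p = 0.2;
coarse dropout of 1–8 rectangles, each 1/400–1/100 of the image area, with
p = 0.3, filled with the per-channel dataset mean (a fill convention this
package fixes; mean-fill is least informative to the classifier).
Percent magnitudes are multiplicative factors on the normalized scale.
Evaluation preprocessing is deterministic: resize 1.1×, center crop,
normalize to [−1, 1].

## Data handling

Datasets are identity-folder trees (`001.aa/…`) with optional YOLO-format
face boxes and a CSV manifest carrying per-image source-group ids (the video
or capture event an image came from). Pixel boxes are 0-based and half-open
(floor the min corner, ceil the max) for unambiguous crop arithmetic.

The train/test split is group-aware: whole groups move to one side, per
identity, in an order keyed by a seed-dependent hash of the group id (so the
split is invariant to record order), until the identity's test share reaches
the target; an identity with a single group goes entirely to train with a
warning. This encodes the anti-leakage rule — consecutive frames of the
same video are near-duplicates and must not straddle the split — as a
testable contract rather than a manual curation step.

Weighted sampling draws training batches with replacement under per-sample
weights ∝ 1/class-count, making expected class frequencies uniform.

## Interpretability

**Gradient-weighted rollout.** Backpropagating the target-class logit gives
∂score/∂A for every attention matrix A. Per layer: clamp the elementwise
product at zero, average over heads, add the identity (residual path), and
row-normalize; the product of these matrices across layers is the rollout.
The class-token row over patch tokens, reshaped to the patch grid,
bilinearly upsampled and min–max normalized, is the attention map. A
constant map (fully saturated) is returned as all zeros with a warning.

**Gamma correction** `v ← v^γ` is rank-preserving; γ < 1 spreads the map for
visualization, γ > 1 sharpens it for quantitative work. Because ranking is
unchanged, insertion results are identical for a map and any gamma-corrected
version of it — asserted in the tests.

**ROI analysis**: fraction of pixels above a threshold (default 0.30,
interpreted on the min–max normalized map, not as a percentile — a
percentile mode is available) and, when a ground-truth face mask is
supplied, the fraction of above-threshold pixels inside the mask.

**Insertion experiment**: the baseline is a Gaussian-blurred copy of the
image; pixels are restored in descending map order (ties broken by raster
order) on a fraction grid (default 21 uniform points including 0 and 1,
configurable since the printed checkpoints of the source protocol are 10%
and 25%), and the target-class confidence is integrated by the trapezoid
rule. The f = 1 point restores the image exactly. The random-order baseline
repeats the procedure with a uniformly random permutation.

The blur width matters and is recorded wherever used: the default is
sigma 10 at 224-pixel resolution. For the insertion experiment to measure
attention quality the baseline must be uninformative — the blurred image's
target confidence should be near chance 1/K. On the 64-pixel synthetic
benchmark this requires sigma 20 (weaker blur leaves the identity's color
signature intact and the experiment loses sensitivity); the benchmark spec
pins that value.

## Synthetic data generator

Each identity is a stable phenotype: skin hue (spread on a shuffled grid so
no two identities share a hue), landmark geometry (eye spacing/size, nose
and mouth position), a procedural fur texture seed, and a 3×3 marking
pattern whose pairwise L∞ separation is enforced above the render-time
jitter. Faces are drawn as an ellipse with painted landmarks, composited
over a low-frequency background, then subjected to per-image nuisance:
rotation ±10°, translation ±5%, scale ±10%, brightness/contrast ±15%,
foliage-like rectangular occluders with probability 0.3 — the kinds and
magnitudes of variation a field camera sees. Group ids simulate source
videos as contiguous blocks (default 5 images). A preset reproduces the
imbalanced per-identity counts of an 18-individual wild macaque study
population (84–447 images per identity, 3385 total). Default render size is
128 px (64 px in the benchmark) to keep everything desk-scale.

What the generator does **not** emulate: photorealistic anatomy, correlated
appearance between biologically similar individuals (kin, same-sex/same-age
pairs — a major error source in real populations), viewpoint changes beyond
in-plane rotation, motion blur, or temporal appearance drift. Passing the
synthetic benchmark therefore demonstrates that the machinery works end to
end and that attention lands on the identity-bearing region — it does not
predict field accuracy.

## Benchmark problem sizes

The standard benchmark trains the 64-pixel, 4-layer, 64-dimensional,
4-head transformer (65 tokens) from random initialization on 12 identities
× 40 images, group-aware split at 10:1, batch 16, up to 30 epochs with
early stopping — about a minute on one CPU. Because the backbone is tiny
and untrained, its learning rate is 1e−3 (the standard scale for small
transformers from scratch; 3e−5 is a fine-tuning rate for large pretrained
backbones) with the fine-tune cap scaled to 3e−4; all adaptive policies are
otherwise unchanged. The test suite's ablation guard (full recipe vs
focal-only, no mixing) runs a further-scaled 6-identity version of the same
setup over two seeds.

## Known limitations

- The held-out split doubles as the schedule-driving validation signal, so
  scheduling decisions see test metrics. This mirrors the protocol the
  package implements; `train(..., val_ds=...)` accepts a separate
  validation split for leakage-free evaluation.
- Closed-set only: unknown individuals cannot be flagged.
- F1 is reported as the macro average (robust under imbalance); micro-F1,
  which equals accuracy in single-label classification, is logged alongside.
- The numpy engine is single-threaded desk-scale infrastructure; it is not
  intended for 224-pixel, 12-layer training runs.
- The classifier-head reading of "multi-layer fully connected classifier
  with dropouts 0.3 and 0.24 after the first and second FC layers" places
  two hidden FC layers (512, 256) before the output layer, so each printed
  dropout follows an FC layer; this is a recorded interpretation, and the
  hidden widths are configurable.
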