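# Methods

## Problem

Grading a cleavage-stage embryo (day 1–3 after fertilization) requires
counting and measuring its blastomeres and estimating the coverage and
position of cytoplasmic fragments. Blastomeres overlap each other
heavily as they cleave, so they must be segmented as *instances*
(overlaps preserved); fragments are small, numerous and clinically
interesting only in aggregate, so they are segmented *semantically* as
a single coverage map.

## Model

One image encoder feeds two branches that share its embedding grid:

* **Instance branch.** A detector (or ground-truth boxes during
  training) supplies one bounding box per blastomere. A frozen prompt
  decoder turns each box into two corner tokens — random-Fourier
  positional encoding of the normalized corner coordinates plus learned
  corner-type embeddings. A mask decoder runs a two-way transformer
  (token self-attention, token→image and image→token cross-attention)
  between the prompt tokens, a learned mask token and IoU token, and the
  positionally-encoded image tokens; a hypernetwork head dots the mask
  token against upscaled, prompt-conditioned image features to produce
  one mask logit map per prompt, and an IoU head predicts the mask's
  quality ν̃ ∈ [0, 1].
* **Semantic branch.** Four stacked UpBlocks — bilinear 2× upsampling
  followed by four 3×3 convolutions, each with per-channel spatial
  (instance) normalization and ReLU — decode the embedding back to full
  resolution, and a 1×1 projection yields a single fragment-vs-background
  logit channel. With embedding stride 16, the four 2× blocks exactly
  recover the input resolution.
* **Fusion.** The per-instance masks M_i and the shared fragment mask
  M_f are combined by pixel-wise union, M_final = ∪_i M_i ∪ M_f. No
  suppression is ever applied between instances — overlapping
  blastomeres are the norm — and the structured output keeps every mask
  individually. A flattened label map (precedence: fragment over
  higher-score instance over lower-score instance) is provided for
  rendering only.

The training objective is the unweighted sum of the two branch losses.
The semantic branch minimizes soft Dice, `1 − 2TP/(FP + 2TP + FN)` with
probabilistic confusion counts and a smoothing constant ε = 1 in
numerator and denominator. The instance branch sums, over the prompted
instances, pixel-mean focal loss (α = 0.25, γ = 2), soft Dice, and the
squared error between the predicted IoU ν̃ and the IoU of the
*binarized* predicted mask against its ground truth. The sum (not mean)
over instances makes crowded frames weigh more, matching the way the
loss is defined per detected instance; focal is averaged over pixels so
instance count rather than instance area drives that outer sum.

### Relation to promptable-segmentation foundations

The architecture follows the promptable-segmentation design in which a
heavy pretrained image encoder and a two-way mask decoder are fine-tuned
while the box-prompt encoder stays frozen (it only consumes
coordinates). This package deliberately replaces the pretrained ViT-H
encoder with a small convolutional backbone (stride 16, a few ten
thousand parameters) so the whole pipeline can be trained and tested on
one CPU in minutes; a checkpoint adapter slot accepts externally
pretrained weights with the same state-dict layout. The value of the
artifact is the pipeline — losses, fusion, metrics, reporting — not the
scale of the encoder. Consequently its absolute numbers are not
comparable to results obtained with a foundation-scale encoder on real
micrographs.

All neural components run on an in-repo reverse-mode autodiff engine
over numpy (conv2d via im2col, bilinear upsampling as an explicit linear
operator with exact adjoint, single-head attention, AdamW with cosine
decay). Gradients are verified against central finite differences in
the test suite.

## Synthetic data

The generator emulates the structure of a cleavage-stage micrograph:

* an embryo disk (radius 0.42 × image size) bounded by a bright zona
  pellucida annulus;
* 1–8+ blastomeres as rotated ellipses with eccentricity ≤ 0.6, centers
  drawn from a shrinking annulus around the embryo centre. An
  `overlap_target` parameter (default 0.5) caps pairwise mask IoU and —
  when positive — each added cell must reach at least 60% of the cap
  with some neighbour, producing the heavy clustering that makes real
  blastomere segmentation hard. Placement uses rejection sampling
  bounded at 200 attempts and raises when the requested geometry is
  unsatisfiable;
* fragments as random-walk blobs of 3–40 px equivalent radius grown
  until the realized area is within ±20% (enforced; the final blob is
  trimmed to budget) of `fragment_coverage` × embryo area, default
  coverage 0.1;
* rendering: dark background (0.15), cytoplasm (0.35), bright
  blastomere bodies (0.70) with darker rims, zona annulus (0.55),
  fragment speckles (0.90), then Gaussian blur (σ = 0.8 px) and additive
  Gaussian noise (σ = 0.03), clipped to [0, 1].

Identical parameters (including the seed) give bit-identical scenes and
images. Images are single-channel and replicated to three channels at
the encoder input.

What the generator does **not** emulate: Hoffman-modulation-contrast
optics, depth-of-field blur across the embryo, compaction or blastocyst
morphology, debris outside the zona, illumination gradients, and the
annotation noise of human labellers. Passing the desk-scale benchmark
therefore demonstrates that the pipeline's mechanics (prompt-conditioned
decoding, joint two-branch optimization, fusion, metrics) work end to
end, not that the trained weights transfer to clinical images.

## Training regime

Ground-truth blastomere boxes serve as prompts (optionally jittered by
`box_jitter_px`, default off). The image is encoded once per step; every
instance is decoded from the shared embedding; both branches are
optimized jointly from the first step. The prompt decoder is frozen by
default. Optimizer AdamW (lr 2e-3 at desk scale, weight decay 1e-4,
linear warmup over the first 5% of steps then cosine decay to 5% — the
attention blocks converge erratically from a cold start without
warmup); batch size is one frame; the seed fixes
initialization, data order and jitter. Images smaller than the model
size are zero-padded bottom/right and predictions are cropped back —
padding is loss-free, so the inverse is an exact crop.

## Evaluation

Detection: greedy score-descending matching at box IoU ≥ 0.5 ("exceeds
50%" implemented as ≥, which differs only on measure-zero ties);
precision, recall, F1 with the 0/0 → 0 convention; AP by all-point
interpolation of the precision envelope; mAP as the unweighted mean over
classes. For segmentation-derived detections the scored box is the
tight box of the predicted mask, ranked by detector score × predicted
IoU. Pixel metrics: hard-count Dice (both-empty → 1) and symmetric
Hausdorff distance over the full foreground pixel sets with Euclidean
distance (a boundary-only variant is exposed as an option). When
exactly one mask is empty, Hausdorff returns the image diagonal as a
finite sentinel — the convention is otherwise undefined and this choice
is pinned by tests.

## Morphology reporting

Per fused frame: blastomere count, maximum and minimum blastomere area
relative to the image resolution, fragment-to-blastomere area ratio
(fragment area over the area of the *union* of blastomere masks, so
overlap does not deflate the denominator; ∞ sentinel when fragments
exist without blastomeres), and the dominant fragment quadrant (NE, NW,
SE, SW relative to the centroid of all foreground) with the raw
fragment centroid also emitted. Over an ordered sequence, a keyframe
marks a blastomere-count change that persists for at least
`persistence_k` frames (default 3), suppressing single-frame detector
flicker; the first frame is always a keyframe. The persistence rule is
this package's own definition — the underlying post-processing for
keyframe extraction is not standardized — and counts are not forced to
be monotone, since detector errors are real.

## Desk-scale benchmark

The acceptance battery trains the pipeline under fixed study
conditions: 128×128 synthetic frames, embedding dim 32, 200 training /
50 validation scenes, 16 epochs, seed-fixed. On one CPU this takes
minutes. It then measures held-out fragment Dice and Hausdorff, mean
per-instance mask IoU under ground-truth prompts, blastomere mAP under
ground-truth-prompt versus jittered-detector (±5 px) conditions, the
full-versus-no-semantic ablation, and the detector-degradation sweep
(mAP at 0/2/5/10 px jitter, ten seeds). Two orderings observed at full
scale are expected to reproduce qualitatively: ground-truth prompts
outperform noisy detections, and the semantic branch outperforms
detector-driven fragment segmentation.

## Numerical choices and degenerate inputs

* Binarization threshold 0.5 on sigmoid probabilities throughout.
* Probabilities are clamped to [1e-6, 1 − 1e-6] inside the focal loss.
* IoU of two empty masks is 0 (for the MSE target); Dice of two empty
  masks is 1 (agreement on absence); precision/recall/F1 of an empty
  confusion table are 0.
* Empty detection lists yield a fragments-only segmentation, not an
  error; a degenerate (zero-area) box prompt is an error.
* Boxes are 0-based half-open pixel intervals; COCO xywh and polygon
  formats are converted at the file boundary. Masks are written as
  uncompressed column-major RLE, which round-trips pixel sets exactly.
* Polygon rasterization includes a pixel iff its centre lies inside the
  polygon, so integer-vertex polygons cover exactly the corresponding
  half-open pixel box.

## Known limitations

* The encoder is small and trained from scratch; absolute metric values
  on real micrographs would require a pretrained encoder through the
  checkpoint adapter plus a real detector.
* The automatic-prompt mode is a regular grid of boxes — a deliberately
  simple stand-in for promptless mask generation, sufficient to show
  that masks without a detector carry no class identity, not to
  reproduce any particular promptless system.
* Fragment blobs are a stand-in, not a claim about the size/shape
  statistics of real fragmentation.
* Frame indices, not hours, are reported for cleavage timing: frame
  rate metadata is out of scope.
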