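# Methods

This note documents the models and procedures implemented in `sgdiff`, the
assumptions behind them, the defaults and why they were chosen, and what the
bundled synthetic data can and cannot establish.

## Problem setting

Interactive surgical simulation needs image synthesis that a user can steer
precisely: move an instrument, swap its type, remove it. Text prompts are
too coarse and segmentation masks are tedious to edit, so the package
conditions a denoising diffusion model on **scene graphs**: one node per
object class with its normalised centroid, bounding-box extents and pixel
area, and a directed edge between every ordered node pair carrying one of
six spatial relations (`left_of`, `right_of`, `above`, `below`, `inside`,
`surrounding`). The workflow has five trained components: two discrete
latent codecs (images, masks), two graph encoders pre-trained to capture
local and global scene information, and the conditional denoiser.

## Synthetic scenes

The generator emulates the structure of anterior-segment (cataract) surgery
frames: a quasi-circular layered anatomy — sclera disk, iris annulus and
pupil disk sharing a jittered centre — 0–3 elongated instruments entering
from the frame border as rotated rectangles, and optional auxiliary border
strips (tape, retractor). Classes: 1 background, 3 anatomy, 4 instruments,
2 auxiliary. Appearance is flat per-class colour plus Gaussian pixel noise
(σ = 0.03); palette colours are separated by ≥ 0.26 in max-channel
distance so colour identity is unambiguous under the noise. Paint order is
anatomy < auxiliary < instruments, matching scenes where instruments
overlay tissue. Everything is a pure function of (config, seed); datasets
use per-index seed substreams so scene *i* is independent of how many
scenes are drawn.

What the generator does **not** model: real texture, specular highlights,
illumination changes, deformation, video continuity, multiple instances of
one class. Tests passing on these scenes establish the machinery
(extraction, pre-training, conditioning, evaluation), not performance on
real surgical frames.

## Graphs from masks

One node per non-background class present in the mask (classes are
instance-like here; multi-instance support is out of scope). Centroids are
means over pixel centres (+0.5), normalised by canvas width/height;
bounding boxes are half-open and tight; area is the pixel fraction. A
node's box for relation assignment and detection scoring is **centred on
its centroid** with the stored extents (clipped to the canvas): this keeps
the JSON schema minimal, makes `move` edits translate the box rigidly, and
coincides with the tight box for symmetric regions. Relations: strict
containment decides `inside`/`surrounding`, otherwise the dominant axis of
the centre displacement decides, with |dx| = |dy| resolving to the
horizontal branch and exactly coincident centres falling back to `left_of`
(deterministic; only reachable for degenerate inputs). Edits (move,
retype, delete, add) always rebuild all edges from the surviving nodes —
O(n²) with n ≤ 9.

## Latent codecs

Each codec is a vector-quantised autoencoder over non-overlapping f×f
patches (f = 4 by default): per-patch MLP encoder to a `code_dim`-vector,
nearest-neighbour codebook lookup (ties to the lowest index), per-patch MLP
decoder. Masks enter one-hot and decode to class logits trained with
cross-entropy; images use mean squared error. The codebook is maintained by
exponential-moving-average updates (decay 0.99), seeded from encoder
outputs on the first batch, with dead codes (unused for 100 updates)
re-seeded from the current batch. The straight-through estimator passes the
decoder gradient to the encoder; a commitment term (weight 0.25) keeps
encoder outputs near their codes.

Two non-obvious choices:

* **Positional embeddings** are added inside the encoder and decoder
  (learned, per latent position). A pure per-patch codec yields latents
  whose spatial mean-pool is blind to *where* content sits, which destroys
  the global pre-training target; the positional terms play the role of a
  convolutional encoder's wide receptive field. They fix the latent grid
  size (`latent_size`), which the pipeline sets to canvas/f.
* The adversarial (patch-discriminator) loss is available behind
  `use_adversarial` but **off** by default: the pipeline needs the codecs
  only as embedding providers, and plain VQ training is stable and fast on
  a CPU.

Defaults: image codec 128 codes × 16 dims (the image latent is the
diffusion state, so it is kept compact); mask codec 256 codes × 32 dims
(richer targets help the contrastive stage); hidden width 96; 12 epochs of
Adam at 3e-3.

## Graph encoders

Stacked message-passing layers: each layer updates
`h_v ← relu(W [h_v ; agg_u msg(h_u, r_uv)])` where `msg` is an MLP over the
sender state concatenated with a learned 8-dim embedding of the edge
relation, and `agg` is mean over in-edges (sum and max are available; all
are permutation-invariant, which the tests check to 1e-5). Nodes without
in-neighbours aggregate a zero message; the empty graph maps to the
all-zero embedding, which doubles as the null conditioning. Defaults: 3
layers, hidden 64, output 64 for the pipeline (128/128 for stand-alone
use); mean-pooled readout plus a linear projection.

## Local pre-training (masked-latent reconstruction)

For each sample a present non-background class is drawn uniformly and the
image pixels inside its tight bounding box are replaced by the dataset mean
colour (a fill at the data's centre of mass avoids trivially detectable
masked regions). Full and masked images are embedded by the frozen image
codec, and a small transformer (2 pre-LN blocks, width 64, single-head
attention) is trained jointly with the local graph encoder to predict the
full latent grid from the masked one; the graph embedding enters as one
token prepended to the latent token sequence. The loss is the mean squared
error over **all** latent positions (not only the masked box). Masking
happens in pixel space before encoding.

The operational meaning of "local information" is a falsifiable property:
with paired seeds, the graph-conditioned run must reach a strictly lower
held-out loss than a control whose graph embedding is zeroed. At 32×32
with 512 scenes and 30 epochs the conditioned run sits roughly 10% below
the control; with only ~300 scenes the jointly trained encoder overfits
and the margin vanishes — the dataset size is part of the study
conditions, not a tuning knob.

## Global pre-training (contrastive mask alignment)

The global encoder aligns graph embeddings with **mask** embeddings — not
image embeddings, whose neighbourhood structure follows anatomy appearance
rather than instrument configuration. Mask embeddings are the spatial
mean-pool of the frozen mask codec's latent grid through a learned linear
head. The loss is the softmax-style negative log ratio over dot products
(one compliant mask, k non-compliant masks sampled uniformly without
replacement from other frames, pixel-identical masks rejected), evaluated
with log-sum-exp max-subtraction.

The dot products are deliberately **unnormalised**: the formula has no
temperature, and with L2-normalised embeddings the logits are confined to
[−1, 1], leaving the softmax so flat that training never leaves chance
level. With free norms the model learns its own effective temperature.
k = 12 by default; k = 8 already beats the ln(k+1) chance bound easily, but
the retrieval precision (compliant mask ranked first against 15 negatives
for ≥ 70% of held-out frames) needs the extra negatives plus cosine
learning-rate decay (3e-3 → 1.5e-4 over 110 epochs).

## Conditional diffusion

Standard DDPM: linear β from 1e-4 to 0.02 over T = 200 steps (T = 1000 is
a config change away), forward marginal `x_t = √ᾱ_t x_0 + √(1−ᾱ_t) ε`,
training loss `E‖ε − ε_θ(x_t, t, c)‖²` with t uniform on {1..T}. The
conditioning c is the concatenation of the frozen local and global graph
embeddings (128 dims); with probability 0.2 a sample's conditioning is
replaced by the all-zero null embedding, so one network serves both
guidance branches. Sampling is ancestral with posterior variance β̃_t, a
deterministic final step, and classifier-free guidance
`ε′ = (1+ω) ε_θ(x_t,t,c) − ω ε_θ(x_t,t)` at ω = 2.0 by default.

Two denoisers share the training/sampling code. The 2-D toy problems use
an MLP with sinusoidal time embeddings, per-block adaptive layer-norm
(FiLM) conditioning, and a conditioned input-skip connection — without the
skip, the identity-like component of ε-prediction (ε ≈ √(1−ᾱ_t)·x_t at
high noise) cannot pass a narrow hidden layer and training stalls near the
trivial loss. The latent-space pipeline uses a transformer over spatial
tokens (2×2 or 4×4 groups of latent cells): pre-LN blocks with FiLM
conditioning before attention and before the MLP, plus a learned
projection of the conditioning onto per-token features, so "paint class k
near position p" is directly expressible rather than having to be
assembled from a global modulation signal. Token weight sharing is the
spatial inductive bias that a flattened-input MLP lacks; a convolutional
UNet would be the natural choice at 128×128 on a GPU.

Conditioning embeddings arrive with arbitrary per-dimension offsets and
scales (the contrastive stage deliberately grows norms), so each dimension
is standardised inside the denoiser with statistics frozen at training
time, and the dropped/unconditional branch is a learned null token rather
than the raw zero vector (the zero vector of the untransformed space is no
longer distinguished after standardisation).

Latents are standardised by global scalar mean/std before training and
un-standardised at sampling time; sampled (continuous) latent grids are
decoded by the image codec decoder without re-quantisation, as usual for
latent diffusion.

## Reverse-workflow evaluation

Generated images are converted back into object lists and compared with
their conditioning graphs. For synthetic scenes the detector is
rule-based: pixels within a max-channel tolerance band (0.13) of a class's
palette colour are grouped into connected components after a binary
closing (bridging gaps up to ~10% of the canvas, so a class region split
by a thin instrument stays one object); components above 0.4% of the
canvas count. By default the detector emits **one detection per class** —
the union box of that class's surviving components — because the entire
package treats classes as instance-like (one graph node per class), and
graph extraction itself computes one box per class over all of its pixels;
this is the exact mirror of the forward direction. A per-component mode
remains for palettes where one class can appear as several genuine
instances, and a learned detector can plug into the same interface for
real data.

Scoring: greedy one-to-one matching of same-class (node, detection) pairs
by descending IoU — an exhaustive-enumeration oracle in the tests confirms
greedy is adequate at these cardinalities. Reported: mean best-IoU over
graph nodes (unmatched → 0), the fraction of nodes matched at IoU ≥ 0.5
(an alternative aggregation, since "IoU at a threshold" can be read either
way), and F1 at the 0.5 threshold. The package's end-to-end check compares
the mean IoU of matched conditioning against a shuffled-conditioning null
(same images, graphs rotated across images) and requires a ≥ 3-standard-
error paired separation.

Diversity and fidelity are computed from a pluggable feature embedding
(default: flattened pixels; the pipeline uses the trained image codec's
pooled latents): mean pairwise RMS feature distance for diversity, the
Fréchet distance between Gaussian moment fits for the FID-style score, and
unbiased MMD² with the polynomial kernel (x·y/d + 1)³ for the KID-style
score. These follow the standard formulas but use the package's own
feature spaces, so their absolute values are not comparable to
Inception-based numbers reported elsewhere.

## Problem sizes

The default experiment ("toy defaults", `sgdiff.pipeline.toy_config`):
32×32 canvas, 512 training scenes, 50 held-out evaluation graphs; image
codec at patch factor 2 (16×16×8 latents), mask codec at factor 4
(8×8×32), 14 epochs each; local pre-training 30 epochs; global 110 epochs
with k = 12 negatives; diffusion 100 epochs at batch 64 with a width-96,
depth-3 token transformer; T = 200; ω = 2.0. A 64×64 canvas and larger
budgets are configuration changes; the pipeline code is size-agnostic.

## Numerical conventions and degenerate inputs

* Repo-global coordinates: origin top-left, x rightward, y downward,
  normalised to [0, 1]; pixel boxes half-open.
* Quantiser ties break to the lowest codebook index.
* `relation_between` raises on zero-area boxes; `iou` returns 0 for them.
* An all-background mask yields the empty graph; the empty graph encodes
  to the zero embedding and conditions like a dropped conditioning.
* β = 0 schedules are permitted as degenerate test inputs (ᾱ ≡ 1).
* All floats are float64; permutation invariance of pooled GNN readouts
  holds to reduction-order rounding (< 1e-5).

## Known limitations

* **Thin-instrument synthesis.** At the default working size the samplers
  reproduce the layered anatomy faithfully but do not reliably synthesize
  the 2–3-pixel-wide instrument shapes, even under oracle conditioning on
  exact node geometry and with several times the default training budget.
  The codec preserves instruments and the graph embeddings demonstrably
  carry instrument identity, so the bottleneck is the denoiser's capacity
  to commit to sharp, multimodal localized structure — the role a
  convolutional UNet plays at full scale on a GPU. End-to-end coherence
  separation versus the shuffled-conditioning null therefore rests mostly
  on anatomy geometry, and edit-responsiveness measurements that depend on
  detecting instruments in samples are not meaningful at this scale; the
  test suite asserts both properties as specified and reports the failures
  rather than weakening them.
* At this scale, conditioning diffusion on the local embedding alone
  scores slightly higher coherence than the fused local+global
  conditioning: the contrastive global embedding helps retrieval but adds
  little geometric signal for the denoiser.
* The rule-based detector presumes the synthetic palette; real images need
  a learned detector behind the same interface.
* One node per class: scenes with repeated instrument types are out of
  scope by design.
* The denoisers tie a checkpoint to their latent grid size.
* Feature-space FID/KID/diversity numbers are internally consistent but
  not comparable across feature extractors.
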