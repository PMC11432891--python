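# Methods

## Overview

`dfslim` implements a one-shot, single-round architecture search for
ViT-style medical image segmentation encoders, plus a directional-field (DF)
pixel-correction module. The search attaches learnable multiplicative masks
`z` to three kinds of searchable sites — per-head feature dimensions of
multi-head self-attention (MHSA), hidden dimensions of the MLP block, and
patch tokens — and co-trains weights and masks under

    min_{W,z}  L_CE( f(z · T(W, x)), y )  +  Σ_g w_g ‖z_g‖₁

where `g` ranges over the three mask groups. The L1 term shrinks mask
magnitudes toward zero while the cross-entropy term defends the dimensions
the task needs, so after training the magnitude of each mask scores that
site's global importance. Any budget's subnet can then be read off a single
ranking with no further search.

### Masked forwards

For head *i* of layer *l* with mask `z ∈ R^d`:

    A_i = softmax( (q_i·z)(k_i·z)^T / √d ),   O_i = A_i (v_i·z)

and the block output is the projection of `[O_1 … O_H]`. The same `z`
multiplies q, k and v; the softmax temperature always uses the *full* `d`,
with no mask-dependent correction. The MLP applies its mask to the hidden
activation, `t_e = f1(t)·z_m`, output `f2(t_e)`. Patch masks pass through
`tanh` before scaling token rows — bounding the scale in (−1, 1) keeps patch
masks from exploding — and are applied at the entry of every encoder block
(a patch has an independent mask per layer).

MHSA/MLP masks are raw reals, deliberately unclamped; the L1 penalty
controls their scale. Importance scores are `|z|` (`|tanh z|` for patches):
a large-magnitude negative mask still transmits signal, so elimination
targets low influence, not low signed value.

### Binarized semantics and slicing

Every searchable linear layer stores one super-weight matrix at maximal
width; a subnet is a set of row/column slices of it. The package's central
equivalence contract — slicing the supernet equals masking it — is stated
for *binarized* masks (kept → 1, dropped → 0, patch tanh bypassed). For
MHSA/MLP dims this equivalence is exact because masks multiply activations
after their biases. For patches it is **not** the continuous zero limit:
a token scaled to zero still exposes its key/value projection *biases* to
every softmax, whereas a removed token is absent from the attention
normalisation. The binarized forward therefore excludes dead tokens from
attention (−∞ key logits) and zeroes their rows; under that semantics the
sliced model reproduces the masked one to float precision. The continuous
search phase uses plain multiplicative masks throughout.

### Budget selection

Budgets are *global per kind*: the top `⌈fraction × total⌉` scoring sites
network-wide are kept, so different heads and layers end up with different
widths — the point of a continuous search space. Ceiling is used so a stated
budget is never undershot. Patch kept-sets are then made monotone down the
depth (running intersection: a patch eliminated at layer *l* stays
eliminated later); only removals are ever applied. Fully-emptied heads are
removed whole (the projection input shrinks); a layer whose patch set would
empty raises an error rather than producing a degenerate softmax. Dropped
patches leave zero rows at their decoder grid positions, matching the
zero-mask limit on the decoder side.

Parameter accounting is closed-form: each kept MHSA dim owns `3(D+1)` q/k/v
weights+biases plus a `D`-wide projection row; each kept MLP dim owns
`(D+1) + D`. FLOPs are reported as multiply–accumulates (1 MAC = 1 FLOP,
encoder matmuls only; stated in every report): token-wise linears scale with
the per-layer live-token count `N_l`, attention score/apply terms with
`N_l²`.

## Direction-field module

Ground truth: for every tissue pixel *m*, with *b* its nearest boundary
pixel of the same class region (exact Euclidean distance transform with
nearest-site indices; ties resolve to the transform's first site),

    D(m) = (m − b) / |m − b|,

pointing *inward* (from boundary toward the pixel); background and boundary
pixels carry (0, 0). A boundary pixel is a tissue pixel with a 4-connected
neighbour of a different class; image-border pixels count as boundary.
Coordinates are (x = column, y = row), 0-based, pixel centres at integers;
channel 0 is x, channel 1 is y.

The learned field head is a 1×1 convolution from the 64-channel
pre-classifier feature map to 2 channels, supervised by mean squared error
against the ground-truth field over tissue pixels only (background targets
are zero vectors and would otherwise dominate), weight 1.0 added to the
segmentation loss. Rectification iterates

    F_i(p) = F_{i−1}(p_x + D(p)_x, p_y + D(p)_y),   i = 1..N  (default N = 5)

with bilinear sampling, border clamping, and the field held fixed across
iterations. The final scores fuse `[F_N, F_N′]` through a 1×1 classifier
initialised as the identity on the F_N block — an untrained DF branch
reproduces the plain classifier exactly, so enabling DF can only change the
model through learning.

Two deliberate gradient choices, both documented here because the reference
formulation leaves them open: (1) the displacement field acts as a constant
during rectification (gradients flow through the sampled features; the head
is trained by its own supervision term, not through resampling
coordinates); (2) the field head reads the trunk features through a
stop-gradient, so the auxiliary field task cannot degrade the segmentation
features it hangs off. Without (2) we observed the field loss competing
with the cross-entropy on the small shared trunk.

An alternative prose description of rectification — thresholding vector
lengths and walking 8-neighbourhoods — is not implemented: it specifies no
threshold and is superseded by the fixed-N bilinear iteration above.

## Full model

Convolutional stem (two 3×3 stages, the second stride-2) → non-overlapping
patchify + linear embedding + learned positional embedding → L masked (or
sliced) transformer blocks (pre-LN, residual) → decoder (nearest-neighbour
×2 upsampling, 3×3 convs, skip connections from both stem stages) → 64
feature channels → classifier / DF module. The reference architecture's
encoder–decoder internals are not prescribed at this scale; this compact
layout keeps every searchable mechanism intact while training in minutes on
a CPU. Enabling DF adds exactly (64·2+2) + (2C·C+C) parameters (field head
+ fusion).

Training uses AdamW (lr 1e-3, weight decay 1e-2, decay skipped for masks
and layer-norm parameters), mini-batch CE averaged over pixels, the L1
penalty added once per step. Defaults w_mhsa = 2e-4, w_mlp = 4e-4,
w_patch = 1e-4. The three-step workflow is: search 50 epochs (weights and
masks jointly) → rank and slice at the budget → retrain 50 epochs with the
same optimiser and no sparsity penalty. All stages are deterministic under
a seed (pure-numpy substrate, hand-rolled AdamW, seeded shuffling).

## Synthetic data

**Phantoms** emulate short-axis cardiac MR geometry: a bright elliptical
cavity (LV-like, class 3), a mid-grey myocardial ring strictly between
cavity and background (MYO-like, class 2), an adjacent darker crescent
(RV-like, class 1), with randomized centres, radii, eccentricities and
intensities, Gaussian boundary blur (σ = 1 px) and additive Gaussian noise
(σ = 0.08 in [0,1] intensity units). Labels are the pre-blur geometry.
Degenerate geometries are rejected and resampled. Ring thickness is
0.06–0.10 of the image side and LV radius 0.10–0.15 — anatomically
plausible proportions. What phantoms do *not* model: MR physics (bias
fields, coil profiles), pathology subgroups, inter-slice anisotropy, or
clinical resolution — at 224² a 5-px displacement is small relative to the
myocardium, at 32² it is not (see Limitations). Volumes for NIfTI exercise
stack one geometry with slice-wise erosion toward the apex.

**Planted-importance tasks** make ranking recovery decidable: inputs are
token arrays in which only k designated feature channels carry the label
mean (amplitude 2 over N(0,1) noise); an identity v/o routing maps channel
h·d+j onto head-dim (h, j), so exactly those MHSA dims are informative. The
probe classifier has no residual path (signal must pass the masked
activations) and a zero-initialised head, so the CE gradient on the masks
vanishes at step one and the L1 penalty acts immediately while the head
learns which dims matter. Analogous constructions exist for MLP dims
(identity f1) and patches (planted tokens).

## Problem sizes used by the test suite and acceptance script

Desk-scale settings chosen so the full suite trains dozens of models: toy
equivalence checks on L=2, H=2, d=4, D=8, M=16, N=16; planted recovery on
L=1, H=4, d=8 (32 MHSA dims, 8 planted) over 20 seeded 30-epoch searches;
the end-to-end benchmark on 32×32 phantoms (patch 8, 16 tokens, D=20,
M=40 — dims chosen so the 70% budgets land on whole sites and the
searchable-parameter reduction at 70/70 budgets is exactly 30%), 60
phantoms per run in the suite and 200 in the acceptance script, split
7:1:2.

## Known limitations

- The rectification step is one pixel per iteration by construction (unit
  vectors); its benefit therefore depends on structure thickness in pixels.
  At 32×32 the myocardial ring is 2–3 px thick and N = 5 iterations read
  across it, so field-guided correction degrades the ring class even with
  the ground-truth field — replacing the prediction by its rectified
  version lowers Dice. At clinical resolution the same displacement is
  small relative to anatomy. The end-to-end DF comparison in the test suite
  runs at this unfavourable scale and treats "DF ≥ plain in a majority of
  seeded runs" as an empirical outcome, not a foregone conclusion.
- Masks multiply activations, so a "removed" patch differs from a
  zero-masked one in attention normalisation; the binarized semantics above
  is the package's resolution of that gap.
- The FLOP/parameter accounting covers the searchable encoder; stem,
  decoder and DF parameters are counted separately and budgets do not
  constrain them.
- autograd's reverse-mode numpy is the differentiation engine; two custom
  primitives (im2col, bilinear sampling) carry hand-written VJPs for speed
  and are gradient-checked against finite differences in the tests.
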