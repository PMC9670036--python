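# Methods

This note documents the models and procedures implemented in `patchgraph`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic fixtures do and do not establish.

## Pipeline overview

A slide raster is tiled into non-overlapping `patch_size` squares on a
regular grid (stride `round(patch_size · (1 − overlap))`; partial border
tiles are dropped, not padded, so patch statistics stay uniform).  A patch is
kept when at most half of its pixels are background; a pixel is background
when it is near-white (`min(R,G,B) ≥ 220`) or nearly achromatic
(`max − min ≤ 15`).  The area threshold (strict: exactly 50 % background is
kept) is a contract of the pipeline; the per-pixel rule is a standard
brightness/saturation heuristic for eosin-stained tissue and is overridable
(`white_min`, `saturation_max`) because scanners and stains vary.

Kept patches are embedded by the contrastive backbone, joined into a graph by
grid adjacency, and classified by the graph-transformer.  Saliency maps
reverse the pipeline: token relevance → pooled-node relevance → node
relevance → pixel footprints.

## Contrastive patch embedding

The encoder is a residual CNN trained with the normalised-temperature
cross-entropy objective over in-batch positives/negatives (both orderings of
each positive pair are averaged).  Defaults:

- temperature τ = 0.5 — the canonical value for this loss family;
- augmentations: random crop with area scale in [0.5, 1.0] resized back,
  colour jitter with a single strength scalar 0.5 (brightness/contrast/
  saturation factors in 1 ± 0.8·s, hue rotation ±0.2·s·π), Gaussian blur
  σ ∈ [0.1, 2.0] applied with probability 0.5.  No-op settings reproduce the
  input bit-for-bit, which the determinism tests rely on;
- optimiser: Adam, initial learning rate 1e-4, cosine-annealed to 0;
- projection head: two dense layers (width = feature dim, output 128, or the
  feature dim itself for narrow backbones), discarded after training.

Two backbone presets exist: `resnet18` (4 stages of 64/128/256/512 channels,
two residual blocks each, 512-d features) for real slides, and `tiny`
(2 stages of 16/32 channels, one block each, 32-d features) which every test
and the acceptance study use.  Stage openings are stride-2 3×3 convolutions
throughout; features are global-average-pooled.

Backbone features are non-negative with a large shared mean, so the pipeline
z-scores node features across the cohort (statistics fitted on training
graphs) before the model's input projection.  This is a conditioning step
only; it does not change separability.

## Graph construction

8-connectivity (Chebyshev distance 1 on grid indices) is the default; 4-
connectivity is available.  Row sums of the binary adjacency lie in [1, 8]
for connected multi-patch slides.  Isolated nodes (possible after aggressive
filtering of fragmented tissue) are permitted with a warning and carry only
their self-loop in Â — downstream stages accept them.  When patches overlap,
adjacency is still defined on grid indices, not pixel distances, so the graph
topology is invariant to the overlap setting.  Graph bundles serialise to
HDF5 with a sparse edge list (node counts can reach thousands on real
slides).

## Graph-transformer

- Graph convolution: `H ← ReLU(Â H W)`, no bias, input initialised with the
  projected node features.
- Min-cut pooling: `S = row-softmax(H W_s)`, `X_pool = Sᵀ H`.  Auxiliary
  losses follow the relaxed normalised-cut formulation: the cut term
  `−Tr(SᵀAS)/Tr(SᵀDS)` lies in [−1, 0] (defined as 0 for edgeless graphs,
  where the objective is vacuous), and the orthogonality term
  `‖SᵀS/‖SᵀS‖_F − I/√n_clusters‖_F` lies in [0, √2].  Both are weighted 1.0
  by default and added to the cross-entropy.  The pooled adjacency
  `Sᵀ A S` (diagonal removed, re-normalised) is recorded for inspection; the
  transformer itself uses no positional encoding — position information lives
  entirely in the graph stages, which is what makes the forward pass exactly
  permutation-invariant.
- Transformer: pre-norm blocks, `t′ = MSA(LN(t)) + t`,
  `t_out = MLP(LN(t′)) + t′`, qkv and head-mixing projections without bias,
  GELU in the MLP.  The class token is a learnable vector initialised from a
  truncated normal (std 0.02).  The prediction head is a single linear layer
  on the layer-normalised class-token output — the minimal faithful readout.
- Config presets: `paper_settings` (hidden 64, one GC layer, 3 blocks,
  8 heads, MLP 128, 100 clusters), `table_best` (hidden 128, 3 GC layers,
  3 blocks, 120 clusters) and `desk_scale` (hidden 32, one GC layer,
  2 blocks, 4 heads, 16 clusters) for CPU-scale work.  The first two reflect
  two published settings that are not mutually consistent; neither is
  asserted as canonical, both are exposed.

Training uses Adam with a step-decay schedule (1e-3, then 1e-4 at step 30 and
1e-5 at step 100 by default) and batches of 8 graphs.  Batches are formed by
loop-accumulating gradients over the graphs of a batch: for disjoint graphs
this is mathematically identical to block-diagonal batching of the GC stage
(pooling is per-graph either way) and keeps one code path for any mix of
graph sizes.  A stratified validation split (20 % by default, or an explicit
validation set) selects the returned state by validation loss; the earliest
best step wins ties.  All randomness (init, batch order, splits) derives from
one integer seed, and two runs with the same seed produce identical loss
trajectories.

## Saliency (gradient-weighted attention relevance)

For a chosen target class the method records each block's attention maps
A^(l) and their gradients ∇A^(l) with respect to the target logit, and
propagates relevance from a one-hot on the target class back through the
stack.  Relevance propagation uses the ε-rule
`R_x = x ⊙ VJP(R_out / (out + ε))` on linear and bilinear operations
(projections, the attention and value matmuls, residual additions — which
split relevance in proportion to contribution), while LayerNorm, GELU,
softmax and scalar scalings pass relevance through unchanged.  Treating the
normalisations as relevance-transparent matters: applying the ε-rule through
a mean-centred operation cancels the relevance total and degrades the maps to
noise.  Block totals are renormalised after each residual split so total
relevance is maintained across layers.

Per block, `Ā^(l) = [E_h(∇A^(l) ⊙ R(n_l))]₊ + I` (mean over heads, positive
part only, identity added so no token suppresses itself), and
`C_t = Ā^(1) · Ā^(2) · … · Ā^(L)`.  The class-token row of C_t over the
pooled-node columns, pushed through the pooling assignment (`C_g = S ·
r_pool`), gives per-node relevance; a forward pass with vanishing attention
gradients yields `C_t = I` and exactly zero node relevance.  Heatmaps min-max
normalise relevance over the kept nodes (an exactly constant relevance vector
maps to 0.5 so the display contract is total), paint patch footprints and
leave background at 0.  IoU curves sweep thresholds {0.1, …, 0.9} by default;
an empty annotation yields IoU 0 with a warning.  The shuffled-relevance
control (same relevance values, randomly permuted over nodes) provides the
localisation baseline.

Relevance propagation runs in double precision regardless of the model's
compute dtype; the stabiliser ε is 1e-9.

## Synthetic fixtures

The generator emulates a 3-class slide task — `normal`, and two tumour
classes distinguished by lesion texture — at desk scale:

- each slide is a (rows+2) × (cols+2) patch raster with a one-patch white
  margin (so background filtering is exercised and the kept-patch count is
  exactly rows × cols), pink noisy tissue with coarse luminance mottling,
  and, for tumour classes, a contiguous near-square lesion block of
  blob-dense (tumor_A) or striped (tumor_B) texture covering ≈
  `lesion_fraction` (default 0.25) of the grid at a random position;
- pixel-level lesion masks accompany every slide, making saliency
  localisation a connected-region-recovery problem with known ground truth;
- grids are drawn from [8, 12] per side by default (emulating variable patch
  counts), patches are 64 px, and the default cohort is 40 slides per class;
- everything is deterministic from the spec's seed.

What the fixtures do *not* emulate: histologic appearance, stain variation,
pen marks and scanner artefacts, fragmented tissue, multi-lesion or
infiltrative growth patterns, magnification pyramids, and patient-level
correlation between slides.  A passing end-to-end suite therefore shows the
machinery is correct and the architecture can learn and localise a planted
texture signal; it does not certify clinical performance.

## Evaluation

Multi-class metrics are one-vs-rest per class: precision, recall
(sensitivity), specificity, accuracy, ROC curves with trapezoidal AUC
(equivalent to the rank statistic with midpoint tie handling) and PR curves
with conservative step-interpolated AUC.  Degenerate denominators yield 0
with a warning.  Cross-validation stratifies folds by slide label with
reproducible assignment; folds are split by slide, not by patient, because a
patient↔slide mapping is dataset-specific — users of real cohorts with
multiple slides per patient should group folds themselves to avoid leakage.

## Numerical choices and problem sizes

- Model parameters and forward/backward computation are float32; oracle
  comparisons and relevance propagation run in float64.
- The autodiff engine stores gradients on every tensor that requires them,
  which is what lets saliency read gradients off intermediate attention maps.
- The acceptance study uses a 120-slide cohort, a 512-patch pre-training pool
  (150 steps, batch 32), one shared extractor, and three training seeds of
  300 steps each on stratified 75/25 splits — sizes chosen so the whole study
  replays from scratch in a few CPU-minutes while keeping ≥ 20 tumour slides
  in each held-out set.
- The extractor is pre-trained once and shared across training seeds,
  mirroring the intended deployment where feature learning and classifier
  training use different cohorts.

## Known limitations

- Slide input is plain RGB rasters (PNG/TIFF); pyramidal formats must be
  flattened to a working magnification first — there is no pyramid-level
  selection logic.
- No stain normalisation or multi-scale bags.
- The numpy engine is single-threaded per operation and CPU-bound; the
  `resnet18` preset is provided for completeness but pre-training it at
  production scale is outside this implementation's performance envelope.
- Min-cut auxiliary loss weights are fixed scalars (default 1.0); no
  annealing is implemented.
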