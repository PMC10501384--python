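# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the synthetic benchmark does and does
not establish.

## Problem setting

m6A site recognition is cast as binary classification of fixed-length RNA
windows (length n, odd) centered on a candidate adenosine: label 1 if the
central A is methylated. The method is transductive over a window set of
size m: all m sequences enter the similarity matrix and the representation
learner together (labels hidden); only the downstream classifier respects
cross-validation folds. This matches how this family of methods is
evaluated; an inductive variant would need fold-restricted graph
construction and is out of scope.

## Representations

**3-mer encoding.** Overlapping 3-mers (n−2 windows) are counted into a
64-vector in fixed lexicographic order (A<C<G<U), normalized to sum to 1.
K = 3 matches codon-scale context; K is exposed but untested beyond 3.
T→U mapping and uppercasing are applied on input; ambiguity codes are
rejected by default (`on_invalid="drop"` discards such records instead) —
their contribution to frequencies is undefined, so they are not guessed at.

**Similarity matrix.** Pairwise Manhattan distances between frequency
vectors (bounded by 2 for probability vectors). Graph operations and the
BCE reconstruction target need affinities in [0,1] oriented "large =
similar", so distances pass through exp(−d/σ) with σ = the median
off-diagonal distance (scale-free, deterministic; fallback mean, then 1,
when degenerate). A `max-complement` transform (1 − d/max d) is available.
The raw distance matrix is kept as the canonical record. No sparsification:
m ≈ 2×10³ is dense-tractable.

**Structure graph.** A Transformer encoder over the 3-mer token streams:
learned 64-entry token embedding + sinusoidal positional encoding
(sin/cos interleaved, frequency 1/10000^{2k/d}); encoder blocks with
multi-head attention, feed-forward (ReLU) sublayers, residual connections
and layer normalization; mean pooling over positions (max pooling
available). Defaults follow the published configuration: d_model 32,
feed-forward 128, 6 blocks, dropout 0.1. Head count: 32 is not divisible
by 6, so the default is 4 heads (per-head width 8); 6 heads are honored
for any d_model divisible by 6. Raw Manhattan distances between pooled
embeddings are unbounded, so the 0.5 edge threshold is applied to a
min-max-normalized *proximity* (1 − normalized distance, diagonal forced
to 1), making the graph invariant to uniform scaling of the embeddings.
The min/max constants are treated as non-differentiable.

## Self-correlation GCN autoencoder

No prior node features exist, so node features start from a learnable
m×m matrix Er. Er is initialized from the input matrix itself (the
similarity matrix) rather than randomly: the node-initialization is
"self-correlation" — each node starts as its own affinity profile — which
gives the autoencoder meaningful geometry at epoch 0 and removes an
arbitrary random-matrix scale. Both branches share the same Er object;
convolution weights are per-branch (a config switch shares them fully).

Each branch applies I = 3 convolutions H' = ReLU(D^{−1/2}ÂD^{−1/2}HW),
Â = ½(A+Aᵀ) + I_m, with widths m→128→64→64, and accumulates a scaled
residual stream R^{(i+1)} = proj(R^{(i)}) + α^{(i+1)}H', α^{(i+1)} =
(i+1)/(I+1); proj is a learned bias-free linear map used exactly where the
running width changes. The literal Laplacian normalization
(diag(deg) − ½(A+Aᵀ), half-power-normalized) is kept behind
`laplacian_variant` for comparison; it is not positive-definite-safe and
is not the default.

**Loss.** L = BCE(sigm(E_sm E_smᵀ), S) + BCE(sigm(E_st E_stᵀ), G_st),
mean over all m² entries per term, computed on logits for stability.
An auxiliary third term reconstructs S from the fused feature matrix so
the fusion blocks receive a label-free training signal (`train_fusion`
off makes them fixed random mixers, the most literal reading).

**Training loop.** Adam at 1e-4 (published rate) over {Er, GCN weights,
Transformer weights, fusion parameters}. The structure graph is refreshed
from the Transformer every `refresh_every` epochs (default 10) and held
fixed between refreshes; the binary thresholding blocks gradients, so a
straight-through estimator passes the loss gradient to the pre-threshold
proximity on refresh epochs. The Transformer pass is checkpointed: the
batch is encoded chunk-wise without graph recording, the loss gradient
with respect to the embeddings is computed once, and chunks are replayed
with recording to accumulate parameter gradients — this caps peak memory
at a few hundred MB regardless of m. A NaN loss aborts with diagnostics;
a non-improving loss over 25 epochs warns but does not fail.

## Fusion

Gates are elementwise: w = sigm(local(e) + global(e)), where each path is
conv1d(k=3, pad 1) → batch-norm → ReLU → conv1d(k=3, pad 1) on the summed
embeddings, and the global path first global-average-pools to one value
per sequence. e^ss = w∘e^sm + (1−w)∘e^st; a second gate mixes e^ss with
the 3-mer vector (projected by a learned linear map, identity-initialized
since the embedding width defaults to 64) into the final feature e^fi.
Batch normalization always uses current-set statistics, consistent with
the transductive setting. The output convolution of every gate stage is
zero-initialized so all gates open at exactly 1/2 — a neutral mixture —
and move away from neutral only under training; randomly-initialized
gates would inject per-feature noise into every fused feature.

The three inputs to fusion are standardized per feature (mean 0, variance
1 over the sequence set; statistics treated as constants) before gating.
The branch embeddings and the raw frequency vector live on scales that
differ by roughly two orders of magnitude, and an un-aligned convex
combination lets one representation numerically erase the others — which
would contradict the design premise that the raw 3-mer representation
contributes indispensably to e^fi. The fusion operations themselves
(`fuse_branches`, `fuse_with_kmer`) remain exact convex combinations of
whatever they are given.

Ablations: `drop-raw` (structure branch + 3-mer only), `drop-trans`
(similarity branch + 3-mer only), `weighted-only` (fixed 0.5/0.5
averages, no gates).

## Evaluation

Stratified 10-fold CV (shuffled, seeded); per-fold MCC, Acc, Sn, Sp, Prec,
F1, AUC (trapezoidal), AUPR (step-interpolated average precision), plus a
`Mean` row of arithmetic column means. Standard definitions are used:
Prec = TP/(TP+FP), F1 = 2·P·S/(P+S). A `paper_literal` flag reproduces a
defective variant seen in print (Prec ≡ Sn, F1 missing its factor 2) for
auditing published tables; it makes Prec identical to Sn and bounds F1 by
one half, so it is never the default. Zero denominators yield 0.
Random forest: 500 trees, sqrt-feature splits, seeded — unstated in the
source configuration, fixed here for reproducibility. The classifier sweep
reuses one fold assignment across backends (paired design) and skips
backends that are not installed (CatBoost, typically) with a warning.

## Synthetic benchmark

The generator emulates the statistical structure the method assumes:
balanced classes, equal-length windows over {A,C,G,U} with a central A in
both classes, and class signal carried by local motif context around the
center. Positives carry a planted consensus context, each non-central
position substituted with probability ε (uniform over the other bases);
the central A is never substituted. Default: m = 2,100 windows of n = 101
(matching the scale of the Arabidopsis benchmark this task is usually
evaluated on), uniform background, ε = 0.

The default motif is the 21-nt GGACU-centered context
`GCAGUCUGGGACUGGAUCGUA`. Its length is a calibration, not a biological
claim: a planted 3-mer shifts its count by ~1 against a background of
~99/64 occurrences (s.d. ≈ 1.2) in a 101-nt window, so a bare 5-mer plant
carries only d′ ≈ 1.3 of linear signal in 3-mer space (Bayes AUC ≈ 0.82)
— far from the "strongly separable" clean regime the recovery checks
define. Separability must moreover survive the pipeline: the convex
fusion roughly halves the k-mer d′ and mixes in embedding noise, and the
random forest exploits rotated embedding coordinates inefficiently. The
21-nt context carries Σ(shift²)/var ≈ 16 (d′ ≈ 4), enough that the fused
features remain separable (mean CV AUC above 0.95) at ε = 0 while ε = 0.4
degrades the pipeline to AUC ≈ 0.6, continuing to chance as ε → 0.5 — the
graded-difficulty profile the end-to-end checks assume.

What passing on this benchmark does **not** show: real m6A windows have
non-uniform base composition, positional dependence beyond one motif,
shared transcript context, and label noise; absolute metric values here do
not transfer to biological data. The benchmark establishes that the
pipeline recovers a planted local signal and ranks conditions correctly.

## Problem sizes and numerical choices

Test- and acceptance-scale runs use m = 400–1,000, two encoder blocks,
30–50 epochs, refresh every 10 — sizes chosen so the full battery runs in
minutes on one core while leaving the published defaults (6 blocks,
lr 1e-4, 3 GCN layers) in the config dataclasses. Everything runs in
float64. Degenerate inputs are handled deterministically: all-equal
embeddings give an all-ones structure graph with a warning; an all-zero
distance matrix under max-complement gives all-ones with a warning; σ
fallbacks as above. Seeds: every stochastic component (generator,
parameter init, dropout, CV shuffling, forest) is driven by an explicit
seed; repeated runs are bit-identical.

## Known limitations

- Transductive by construction; adding unseen sequences requires refitting
  (or the nearest-neighbor attachment heuristic, not implemented).
- The Er matrix is m×m, so memory and compute grow quadratically in the
  dataset size; m beyond ~5×10³ would need a different parameterization.
- The fusion gates are trained only by the label-free auxiliary
  reconstruction; nothing pushes them toward the classification-optimal
  mixture, and on easy datasets the fused features can trail the raw 3-mer
  features slightly.
- The Transformer receives gradient only on refresh epochs (the graph is
  a constant in between), so with few refreshes it stays near its
  initialization; the structure graph then mostly reflects the random
  initial embedding geometry refined by a handful of updates.
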