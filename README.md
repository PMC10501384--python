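# m6atmr

Sequence-only recognition of N6-methyladenosine (m6A) modification sites in
RNA. Given a set of fixed-length RNA windows centered on a candidate
adenosine (the standard framing: 101-nt windows, positive if the central A
is methylated), the package learns per-sequence representations from
*sequence similarity structure* alone — no physicochemical descriptors, no
pretrained language model — and classifies them with a random forest under
stratified 10-fold cross-validation.

## Method

For a window set Ω = {X₁ … X_m}:

1. **3-mer encoding.** Each window is summarized by its normalized
   overlapping 3-mer frequency vector R_X ∈ ℝ⁶⁴ (codon-scale context), and
   by the integer token stream of its 3-mers.
2. **Similarity matrix.** S ∈ ℝ^{m×m} from pairwise Manhattan distances
   d(i,j) = Σⱼ |R_i^j − R_j^j|, mapped to a [0,1] affinity with an RBF
   kernel exp(−d/σ), σ = median off-diagonal distance.
3. **Structure graph.** A small Transformer encoder (sinusoidal positional
   encoding; multi-head softmax(QKᵀ/√d)V attention; feed-forward sublayers)
   embeds each token stream; pairwise Manhattan distances between the
   pooled embeddings are min-max normalized, complemented into a proximity,
   and thresholded at 0.5 into a binary graph G_st ∈ {0,1}^{m×m}.
4. **Self-correlation graph convolution.** With no prior node features,
   a learnable node matrix Er ∈ ℝ^{m×m} (initialized from the similarity
   matrix itself) is passed through three graph convolutions
   H' = ReLU(D^{−1/2} Â D^{−1/2} H W) with scaled residual accumulation
   R^{(i+1)} = R^{(i)} + α^{(i+1)}·H', α^{(i+1)} = (i+1)/(I+1), once with
   A = S and once with A = G_st.
5. **Reconstruction training.** Both branch embeddings are trained as a
   graph autoencoder: L = BCE(sigm(E_sm E_smᵀ), S) + BCE(sigm(E_st E_stᵀ),
   G_st), with G_st refreshed from the Transformer every few epochs
   (straight-through gradient through the threshold) and Adam at 1e-4.
6. **Local–global fusion.** Gates w = sigm(local(e) + global(e)) — two 1-D
   conv stages, the global path adds average pooling — mix the branch
   embeddings (e^ss = w∘e^sm + (1−w)∘e^st) and then mix e^ss with the raw
   3-mer vector into the final feature e^fi.
7. **Evaluation.** Random forest (500 trees) under stratified 10-fold CV;
   reports MCC, Acc, Sn, Sp, Prec, F1, AUC, AUPR, plus ROC/PR curves, a
   paired classifier sweep (LR, SVM, XGBoost, LightGBM, …) and feature
   ablations (drop-raw / drop-trans / weighted-only).

Because no public benchmark ships with the package, `m6atmr.synthetic`
generates balanced benchmark datasets: 101-nt windows with a central A, a
21-nt GGACU-centered consensus context planted in positives, and a
per-position substitution rate ε that degrades the signal continuously.

## Worked example

```python
import numpy as np
from m6atmr import M6ATMR, GcnConfig, SynthConfig, TransformerConfig, generate

records, truth = generate(SynthConfig(m=400, n=101, eps=0.1, seed=1))
model = M6ATMR(records,
               transformer=TransformerConfig(blocks=2, seed=1),
               gcn=GcnConfig(epochs=30, refresh_every=10, seed=1))
result = model.fit()          # representation learning + 10-fold CV
print(result.summary())
```

prints (abridged):

```
                         M6ATMR Results
==================================================================
Sequences:            400 windows of length 101
K-mer order:          3 (64 features)
Similarity transform: rbf
Transformer:          d_model=32, heads=4, blocks=2
GCN:                  layers=3, dims=(128, 64, 64), lr=0.0001
Training epochs:      30 (loss 14.7477 -> 2.4252)
Structure graph:      150638 edges (density 0.941)
------------------------------------------------------------------
10-fold cross-validation (random forest, transductive representation):

         MCC    Acc    Sn    Sp    Prec      F1     AUC    AUPR
Fold
0     0.5507  0.775  0.80  0.75  0.7619  0.7805  0.8562  0.8767
1     0.8000  0.900  0.90  0.90  0.9000  0.9000  0.9650  0.9724
...
Mean  0.6637  0.830  0.84  0.82  0.8271  0.8312  0.8981  0.9071
==================================================================
```

The `Mean` row is the arithmetic mean over folds. The training loss is the
two-term adjacency-reconstruction cross-entropy (plus the fused-feature
auxiliary term); its descent indicates the autoencoder is compressing the
similarity and structure graphs. On the clean ε=0 benchmark the mean CV AUC
exceeds 0.95; as ε rises toward 0.5 the planted signal — and the AUC —
decays toward chance, which is the package's end-to-end sanity battery.

The same pipeline is available from the shell:

```bash
m6atmr synth --m 2100 --n 101 --eps 0.1 --seed 1 --out-fasta bench.fa
m6atmr run -f bench.fa -o out/ --epochs 30 --seed 1
m6atmr sweep -f bench.fa -o out/ --seed 1
m6atmr ablate -f bench.fa -o out/ --mode drop-raw --seed 1
```

To analyze a real dataset, supply a FASTA of equal-length windows with
`label=0|1` header tags (or a two-column TSV via `--labels`); T is accepted
and read as U.

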