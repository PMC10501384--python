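"""Local-global gated fusion of branch embeddings and k-mer features.

Two embeddings of the same sequence are summed, viewed once locally (two
1-D convolutions with batch normalization and ReLU between them) and once
globally (the same stack applied to the global average), and the sigmoid of
the summed views yields an elementwise gate w in (0,1).  The fused vector is
the convex combination w * e1 + (1 - w) * e2.  One gate merges the
similarity-branch and structure-branch embeddings into e_ss; a second gate
merges e_ss with the (projected) raw 3-mer frequency vector into the final
classifier feature e_fi.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, no_grad
from .nn import Linear

__all__ = ["FusionBlock", "FusionPipeline", "fusion_weight", "fuse_branches",
           "fuse_with_kmer", "ABLATION_MODES"]

ABLATION_MODES = ("full", "drop-raw", "drop-trans", "weighted-only")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class _ConvStage:
    """conv(k=3, pad=1) -> batch-norm -> ReLU -> conv(k=3, pad=1).

    The output convolution starts at zero so the stage is initially the zero
    map and the downstream sigmoid gate opens at exactly 1/2; training moves
    it away from neutral only where the loss asks for it.
    """

    def __init__(self, rng: np.random.Generator | None):
        if rng is None:  # fully zero init: the stage is the zero map
            w = lambda: Tensor(np.zeros(3), requires_grad=True)
        else:
            lim = np.sqrt(6.0 / 4.0)
            w = lambda: Tensor(rng.uniform(-lim, lim, 3), requires_grad=True)
        self.w1 = w()
        self.w2 = Tensor(np.zeros(3), requires_grad=True)
        self.b1 = Tensor(np.zeros(1), requires_grad=True)
        self.b2 = Tensor(np.zeros(1), requires_grad=True)
        self.gamma = Tensor(np.ones(1), requires_grad=True)
        self.beta = Tensor(np.zeros(1), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        y = x.conv1d3(self.w1, self.b1)
        mu = y.mean(axis=0, keepdims=True)          # batch statistics
        yc = y - mu
        var = (yc * yc).mean(axis=0, keepdims=True)
        y = yc * ((var + 1e-5) ** -0.5) * self.gamma + self.beta
        return y.relu().conv1d3(self.w2, self.b2)

    def parameters(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2, self.gamma, self.beta]


class FusionBlock:
    """Parallel local and global extraction stages feeding one sigmoid gate."""

    def __init__(self, rng: np.random.Generator | None = None):
        self.local = _ConvStage(rng)
        self.global_ = _ConvStage(rng)

    def parameters(self) -> list[Tensor]:
        return self.local.parameters() + self.global_.parameters()


def fusion_weight(e_a, block: FusionBlock) -> Tensor:
    """Gate w = sigmoid(local(e_a) + global(e_a)); entries strictly in (0,1)."""
    x = _as_tensor(e_a)
    if not np.isfinite(x.data).all():
        raise ValueError("non-finite fusion input")
    local = block.local(x)
    pooled = x.mean(axis=1, keepdims=True)          # global average pooling
    global_ = block.global_(pooled)
    return (local + global_).sigmoid()


def fuse_branches(e_sm, e_st, block: FusionBlock) -> Tensor:
    """e_ss = w * e_sm + (1 - w) * e_st with w gated on e_sm + e_st."""
    a, b = _as_tensor(e_sm), _as_tensor(e_st)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    w = fusion_weight(a + b, block)
    return w * a + (1.0 - w) * b


def fuse_with_kmer(e_ss, e_km, block: FusionBlock) -> Tensor:
    """Final feature e_fi = w' * e_ss + (1 - w') * e_km (same gate form)."""
    return fuse_branches(e_ss, e_km, block)


class FusionPipeline:
    """Both fusion levels plus the k-mer projection, with ablation modes.

    ``d_emb`` is the branch-embedding width; the 64-dim k-mer vector is
    mapped to it by a learned linear projection initialized to the identity
    when d_emb == 64.
    """

    def __init__(self, d_emb: int = 64, d_km: int = 64, seed: int = 0,
                 standardize: bool = True):
        rng = np.random.default_rng(seed)
        self.block_branches = FusionBlock(rng)
        self.block_kmer = FusionBlock(rng)
        self.kmer_proj = Linear(rng, d_km, d_emb, bias=False, identity_init=True)
        self.standardize = standardize

    def parameters(self) -> list[Tensor]:
        return (self.block_branches.parameters() + self.block_kmer.parameters()
                + self.kmer_proj.parameters())

    @staticmethod
    def _zscore(t: Tensor) -> Tensor:
        # per-feature standardization over the sequence set; the statistics
        # are treated as constants so they act as a scale alignment, not as
        # an extra gradient path
        mu = t.data.mean(axis=0, keepdims=True)
        sd = t.data.std(axis=0, keepdims=True) + 1e-8
        return (t - Tensor(mu)) * Tensor(1.0 / sd)

    def forward(self, e_sm, e_st, e_km, mode: str = "full") -> Tensor:
        """Fused features; inputs are standardized per feature first (the
        branch embeddings and the raw frequency vector live on very
        different scales, and an un-aligned convex combination would let one
        representation numerically erase the others)."""
        if mode not in ABLATION_MODES:
            raise ValueError(f"unknown ablation mode {mode!r}; choose from {ABLATION_MODES}")
        e_sm, e_st, e_km = (_as_tensor(x) for x in (e_sm, e_st, e_km))
        if self.standardize:
            e_sm, e_st, e_km = (self._zscore(x) for x in (e_sm, e_st, e_km))
        km = self.kmer_proj(e_km)
        if mode == "weighted-only":
            e_ss = 0.5 * (e_sm + e_st)
            return 0.5 * (e_ss + km)
        if mode == "drop-raw":       # no similarity-matrix information
            e_ss = e_st
        elif mode == "drop-trans":   # no structure-graph information
            e_ss = e_sm
        else:
            e_ss = fuse_branches(e_sm, e_st, self.block_branches)
        return fuse_with_kmer(e_ss, km, self.block_kmer)

    def ablate(self, e_sm: np.ndarray, e_st: np.ndarray, e_km: np.ndarray,
               mode: str = "full") -> np.ndarray:
        """Feature matrix (m rows) for one ablation mode, no gradients."""
        with no_grad():
            return self.forward(e_sm, e_st, e_km, mode=mode).data
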