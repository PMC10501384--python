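"""Transformer encoder over 3-mer token streams and the binary structure graph.

Each sequence's overlapping 3-mer tokens are embedded (64-entry learned
table), summed with a fixed sinusoidal positional encoding, passed through a
stack of standard encoder blocks (multi-head softmax(QK^T/sqrt(d))V attention
plus a position-wise feed-forward sublayer, residual connections, layer
normalization), and mean-pooled over positions into one d_model vector per
sequence.  Pairwise Manhattan distances between those pooled embeddings,
min-max normalized and complemented into a proximity in [0, 1], are
thresholded at 0.5 to give the binary, symmetric structure graph over the
sequence set.  During joint training the thresholding is a straight-through
step: the binary graph is used forward, gradients flow through the
pre-threshold proximity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, no_grad, pairwise_l1
from .nn import Embedding, LayerNorm, Linear

__all__ = ["TransformerConfig", "positional_encoding", "TransformerEncoder",
           "encode_sequences", "build_structure_graph", "structure_proximity"]


@dataclass
class TransformerConfig:
    """Encoder hyperparameters.

    d_model must be divisible by heads; the default pairing is (32, 4).
    Six heads are honored only with a d_model that is a multiple of six.
    """

    d_model: int = 32
    heads: int = 4
    ff_dim: int = 128
    blocks: int = 6
    dropout: float = 0.1
    pooling: str = "mean"
    seed: int = 0

    def __post_init__(self):
        if min(self.d_model, self.ff_dim) <= 0 or self.blocks < 0 or self.heads <= 0:
            raise ValueError("dimensions must be positive (blocks may be 0)")
        if self.d_model % self.heads != 0:
            raise ValueError(
                f"d_model={self.d_model} not divisible by heads={self.heads}; "
                "use heads=4 with d_model=32, or raise d_model")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.pooling not in ("mean", "max"):
            raise ValueError("pooling must be 'mean' or 'max'")


def positional_encoding(L: int, d: int) -> np.ndarray:
    """Sinusoidal position table, shape (L, d).

    Row t: even column 2k holds sin(w_k t), odd column 2k+1 holds cos(w_k t)
    with w_k = 1/10000^(2k/d).  Row 0 is (0, 1, 0, 1, ...).
    """
    if L < 1 or d < 2:
        raise ValueError("need L >= 1 and d >= 2")
    if d % 2 != 0:
        raise ValueError("d must be even (sin/cos pairing undefined for odd d)")
    t = np.arange(L, dtype=np.float64)[:, None]
    k = np.arange(d // 2, dtype=np.float64)[None, :]
    w = 1.0 / 10000.0 ** (2.0 * k / d)
    table = np.empty((L, d))
    table[:, 0::2] = np.sin(w * t)
    table[:, 1::2] = np.cos(w * t)
    return table


class _EncoderBlock:
    def __init__(self, rng: np.random.Generator, cfg: TransformerConfig):
        d = cfg.d_model
        self.heads = cfg.heads
        self.wq = Linear(rng, d, d)
        self.wk = Linear(rng, d, d)
        self.wv = Linear(rng, d, d)
        self.wo = Linear(rng, d, d)
        self.ff1 = Linear(rng, d, cfg.ff_dim)
        self.ff2 = Linear(rng, cfg.ff_dim, d)
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)

    def __call__(self, x: Tensor, drop_mask=None) -> Tensor:
        B, L, d = x.shape
        h, dh = self.heads, d // self.heads

        def split(t: Tensor) -> Tensor:  # (B,L,d) -> (B,h,L,dh)
            return t.reshape(B, L, h, dh).transpose(0, 2, 1, 3)

        # scaling q up front avoids materializing an extra (B,h,L,L) tensor
        q = split(self.wq(x)) * (1.0 / np.sqrt(dh))
        k, v = split(self.wk(x)), split(self.wv(x))
        scores = q @ k.transpose(0, 1, 3, 2)
        attn = scores.softmax(axis=-1) @ v                      # (B,h,L,dh)
        attn = attn.transpose(0, 2, 1, 3).reshape(B, L, d)
        y = self.wo(attn)
        if drop_mask is not None:
            y = y * drop_mask[0]
        x = self.ln1(x + y)
        z = self.ff2(self.ff1(x).relu())
        if drop_mask is not None:
            z = z * drop_mask[1]
        return self.ln2(x + z)

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for mod in (self.wq, self.wk, self.wv, self.wo, self.ff1, self.ff2,
                    self.ln1, self.ln2):
            ps.extend(mod.parameters())
        return ps


class TransformerEncoder:
    """Token streams -> one pooled d_model embedding per sequence."""

    def __init__(self, cfg: TransformerConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.embed = Embedding(rng, 64, cfg.d_model)
        self.blocks = [_EncoderBlock(rng, cfg) for _ in range(cfg.blocks)]
        self._drop_rng = np.random.default_rng(cfg.seed + 1)

    def parameters(self) -> list[Tensor]:
        ps = list(self.embed.parameters())
        for b in self.blocks:
            ps.extend(b.parameters())
        return ps

    def forward(self, tokens: np.ndarray, train: bool = False) -> Tensor:
        """Encode an (m, L) integer token matrix to an (m, d_model) tensor."""
        tokens = np.asarray(tokens)
        if tokens.ndim != 2 or tokens.shape[0] == 0:
            raise ValueError("tokens must be a nonempty (m, L) integer matrix")
        m, L = tokens.shape
        x = self.embed(tokens) + Tensor(positional_encoding(L, self.cfg.d_model))
        p = self.cfg.dropout
        for blk in self.blocks:
            masks = None
            if train and p > 0.0:
                masks = [Tensor(self._drop_rng.binomial(1, 1 - p, size=(m, L, 1))
                                / (1 - p)) for _ in range(2)]
            x = blk(x, masks)
        if not np.isfinite(x.data).all():
            raise FloatingPointError("non-finite activations in encoder output")
        if self.cfg.pooling == "mean":
            return x.mean(axis=1)
        # max pooling: no gradient support needed for this inference-only path
        return Tensor(x.data.max(axis=1))

    def encode(self, tokens: np.ndarray, chunk: int = 200,
               train: bool = False) -> np.ndarray:
        """Gradient-free chunked encoding (bounded memory)."""
        with no_grad():
            outs = [self.forward(tokens[i:i + chunk], train=train).data
                    for i in range(0, len(tokens), chunk)]
        return np.concatenate(outs, axis=0)

    def backward_chunked(self, tokens: np.ndarray, grad_out: np.ndarray,
                         chunk: int = 200, train: bool = False) -> None:
        """Checkpointed backward: re-run each chunk with graph recording and
        inject the matching rows of ``grad_out`` (dLoss/dEmbedding)."""
        for i in range(0, len(tokens), chunk):
            out = self.forward(tokens[i:i + chunk], train=train)
            out.backward(grad_out[i:i + chunk])


def encode_sequences(tokens: np.ndarray, cfg: TransformerConfig | None = None) -> np.ndarray:
    """One-shot functional wrapper: deterministic for a fixed cfg.seed."""
    cfg = cfg or TransformerConfig()
    return TransformerEncoder(cfg).encode(np.asarray(tokens))


def structure_proximity(E: Tensor | np.ndarray) -> Tensor:
    """Pairwise proximity 1 - minmax(L1 distance), in [0, 1], diagonal 1.

    Min and max are taken over off-diagonal distances and treated as
    constants, which makes the output invariant to uniform scaling of the
    embeddings while keeping the gradient path simple.
    """
    if not isinstance(E, Tensor):
        E = Tensor(E)
    m, d = E.shape
    if m < 2:
        raise ValueError("need at least two embeddings")
    D = pairwise_l1(E)                               # (m, m) with gradient
    off = ~np.eye(m, dtype=bool)
    dmin = float(D.data[off].min())
    dmax = float(D.data[off].max())
    if dmax == dmin:
        warnings.warn("all embeddings are equidistant; structure graph degenerates")
        return Tensor(np.ones((m, m))) + (D - D.detach())  # grad path kept alive
    P = 1.0 - (D - dmin) * (1.0 / (dmax - dmin))
    # clip diagonal handling: self-distance 0 maps to >1, force exactly 1
    correction = np.zeros((m, m))
    np.fill_diagonal(correction, 1.0 - P.data.diagonal())
    return P + Tensor(correction)


def build_structure_graph(embeddings: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary symmetric adjacency from pooled embeddings (diagonal forced 1)."""
    P = structure_proximity(np.asarray(embeddings, dtype=np.float64)).data
    G = (P > threshold).astype(np.float64)
    np.fill_diagonal(G, 1.0)
    return G
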