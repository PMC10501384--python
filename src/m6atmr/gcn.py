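"""Self-correlation graph convolutional autoencoder.

Both the [0,1] similarity matrix and the binary structure graph are treated
as adjacencies over the m sequences.  No prior node annotations exist, so
node features start from a single learnable m-by-m matrix ``Er`` shared by
the two branches.  Each branch applies three graph convolutions

    H' = ReLU( D^{-1/2} (Ahat) D^{-1/2} H W ),   Ahat = (A + A^T)/2 + I

and accumulates a scaled residual stream R <- proj(R) + alpha_i * H' with
alpha_i = i/(I+1), which keeps late-layer contributions from vanishing.
Training minimizes the sum of two adjacency-reconstruction binary
cross-entropies, sigmoid(E E^T) against the similarity matrix and against
the structure graph, optionally plus the same reconstruction from the fused
representation; the structure graph is refreshed from the Transformer every
``refresh_every`` epochs with a straight-through gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor, bce_with_logits, no_grad
from .nn import Adam, Linear, glorot
from .transformer import TransformerConfig, TransformerEncoder, structure_proximity

__all__ = ["GcnConfig", "alpha_schedule", "gcn_layer", "SelfCorrelationGcn",
           "reconstruction_loss", "train", "TrainingResult"]


@dataclass
class GcnConfig:
    layers: int = 3
    hidden_dims: tuple[int, ...] = (128, 64, 64)
    learning_rate: float = 1e-4
    fusion_learning_rate: float = 1e-4   # gate heads; kept as a separate group
    epochs: int = 200
    refresh_every: int = 10
    seed: int = 0
    structure_threshold: float = 0.5
    share_branch_weights: bool = False
    laplacian_variant: bool = False
    train_fusion: bool = True
    patience: int = 25

    def __post_init__(self):
        if self.layers < 1:
            raise ValueError("need at least one layer")
        if len(self.hidden_dims) != self.layers:
            raise ValueError("hidden_dims must list one width per layer")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


def alpha_schedule(i: int, I: int) -> float:
    """Residual scale for layer index i (0-based): alpha = (i+1)/(I+1)."""
    if not 0 <= i < I:
        raise ValueError(f"layer index {i} out of range for I={I}")
    return (i + 1) / (I + 1)


def _normalize_adjacency(A: Tensor, laplacian: bool = False) -> Tensor:
    """D^{-1/2} Ahat D^{-1/2} with Ahat = sym(A) + I (self-loops).

    ``laplacian=True`` normalizes diag(deg) - sym(A) instead (the literal
    Laplacian reading, kept for comparison).
    """
    m = A.shape[0]
    sym = (A + A.transpose()) * 0.5
    if laplacian:
        deg = sym.sum(axis=1, keepdims=True)
        core = Tensor(np.diagflat(deg.data)) - sym
        dinv = (deg + 1e-12) ** -0.5
        return core * dinv * dinv.transpose()
    ahat = sym + Tensor(np.eye(m))
    deg = ahat.sum(axis=1, keepdims=True)           # >= 1 by self-loops
    dinv = deg ** -0.5
    return ahat * dinv * dinv.transpose()


def _gcn_layer_t(H: Tensor, A_norm: Tensor, W: Tensor) -> Tensor:
    # (A_norm @ (H @ W)) ordering keeps the big matmul at m x m x d_out
    return (A_norm @ (H @ W)).relu()


def gcn_layer(H: np.ndarray, A: np.ndarray, W: np.ndarray,
              laplacian: bool = False) -> np.ndarray:
    """Functional single graph convolution on plain arrays."""
    H, A, W = (np.asarray(x, dtype=np.float64) for x in (H, A, W))
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if H.shape[0] != A.shape[0] or H.shape[1] != W.shape[0]:
        raise ValueError("shape mismatch among H, A, W")
    if not all(np.isfinite(x).all() for x in (H, A, W)):
        raise ValueError("non-finite input")
    return _gcn_layer_t(Tensor(H), _normalize_adjacency(Tensor(A), laplacian),
                        Tensor(W)).data


class SelfCorrelationGcn:
    """One branch: learnable Er plus `layers` scaled-residual convolutions.

    ``Er`` may be shared across branches; weights and residual projections
    are per-branch unless configured otherwise.
    """

    def __init__(self, m: int, cfg: GcnConfig, rng: np.random.Generator,
                 Er: Tensor | None = None, init_matrix: np.ndarray | None = None):
        self.cfg = cfg
        self.m = m
        if Er is not None:
            self.Er = Er
        elif init_matrix is not None:
            # learnable node-initialization generated from the input matrix
            # itself (no prior node annotations exist)
            self.Er = Tensor(np.array(init_matrix, dtype=np.float64, copy=True),
                             requires_grad=True)
        else:
            self.Er = glorot(rng, m, m)
        widths = [m, *cfg.hidden_dims]
        self.weights = [glorot(rng, widths[i], widths[i + 1])
                        for i in range(cfg.layers)]
        # residual-stream projections where the running width changes
        self.projections: list[Linear | None] = []
        for i in range(cfg.layers):
            if widths[i] != widths[i + 1]:
                self.projections.append(Linear(rng, widths[i], widths[i + 1],
                                               bias=False))
            else:
                self.projections.append(None)

    def parameters(self, include_er: bool = True) -> list[Tensor]:
        ps: list[Tensor] = [self.Er] if include_er else []
        ps.extend(self.weights)
        for proj in self.projections:
            if proj is not None:
                ps.extend(proj.parameters())
        return ps

    def forward(self, A: Tensor) -> Tensor:
        A_norm = _normalize_adjacency(A, self.cfg.laplacian_variant)
        H = self.Er
        R = self.Er
        I = self.cfg.layers
        for i in range(I):
            Z = _gcn_layer_t(H, A_norm, self.weights[i])
            if self.projections[i] is not None:
                R = self.projections[i](R)
            R = R + alpha_schedule(i, I) * Z
            H = Z
        return R


def reconstruction_loss(S_hat: np.ndarray, S_target: np.ndarray,
                        G_hat: np.ndarray, G_target: np.ndarray,
                        eps: float = 1e-12) -> float:
    """Sum of the two mean binary cross-entropies over all m^2 entries."""
    total = 0.0
    for hat, target in ((S_hat, S_target), (G_hat, G_target)):
        hat = np.clip(np.asarray(hat, dtype=np.float64), eps, 1 - eps)
        target = np.asarray(target, dtype=np.float64)
        if target.min() < 0 or target.max() > 1:
            raise ValueError("reconstruction targets must lie in [0, 1]")
        total += float(np.mean(-target * np.log(hat) - (1 - target) * np.log(1 - hat)))
    return total


@dataclass
class TrainingResult:
    """Trained representation state for one sequence set."""

    e_sm: np.ndarray                 # similarity-branch embeddings (m, d)
    e_st: np.ndarray                 # structure-branch embeddings (m, d)
    structure_graph: np.ndarray      # final binary G_st
    log: pd.DataFrame                # per-epoch loss terms
    fusion: "object | None" = None   # trained FusionPipeline (set by caller)
    encoder: TransformerEncoder | None = None
    branches: tuple | None = None


def train(S: np.ndarray, tokens: np.ndarray, cfg: GcnConfig | None = None,
          tcfg: TransformerConfig | None = None,
          e_km: np.ndarray | None = None,
          fusion: "object | None" = None,
          verbose: bool = False) -> TrainingResult:
    """Joint training of Transformer, both GCN branches and fusion blocks.

    Parameters
    ----------
    S : (m, m) similarity matrix in [0, 1] (the similarity-branch adjacency
        and reconstruction target).
    tokens : (m, L) integer 3-mer token streams for the Transformer.
    e_km : optional (m, 64) k-mer frequency matrix; required when
        ``cfg.train_fusion`` and a fusion pipeline is supplied.
    fusion : optional FusionPipeline whose parameters join the optimizer and
        whose fused output contributes an auxiliary reconstruction term.
    """
    import warnings

    cfg = cfg or GcnConfig()
    tcfg = tcfg or TransformerConfig()
    S = np.asarray(S, dtype=np.float64)
    m = S.shape[0]
    if tokens.shape[0] != m:
        raise ValueError("S and tokens disagree on the number of sequences")
    if S.min() < 0 or S.max() > 1:
        raise ValueError("S must be a [0,1] similarity matrix (transform distances first)")

    rng = np.random.default_rng(cfg.seed)
    encoder = TransformerEncoder(tcfg)
    branch_sm = SelfCorrelationGcn(m, cfg, rng, init_matrix=S)
    if cfg.share_branch_weights:
        branch_st = branch_sm
    else:
        branch_st = SelfCorrelationGcn(m, cfg, rng, Er=branch_sm.Er)

    params = branch_sm.parameters() + branch_st.parameters(include_er=False)
    params += encoder.parameters()
    opts = [Adam(params, lr=cfg.learning_rate)]
    use_fusion = cfg.train_fusion and fusion is not None
    if use_fusion:
        if e_km is None:
            raise ValueError("train_fusion requires the k-mer matrix e_km")
        # the gate heads are tiny and freshly initialized; they get their own
        # optimizer so they train on the same schedule as the big components
        opts.append(Adam(fusion.parameters(), lr=cfg.fusion_learning_rate))

    S_t = Tensor(S)
    G_bin: np.ndarray | None = None
    rows = []
    best = np.inf
    since_best = 0
    drop_on = tcfg.dropout > 0
    for epoch in range(cfg.epochs):
        refresh = (epoch % cfg.refresh_every == 0) or G_bin is None
        E_leaf = None
        if refresh:
            # checkpointed encoder pass: encode without recording, attach the
            # embeddings as a leaf, and replay chunks for the gradient later
            rng_state = encoder._drop_rng.bit_generator.state
            E_leaf = Tensor(encoder.encode(tokens, train=drop_on),
                            requires_grad=True)
            P = structure_proximity(E_leaf)
            G_bin = (P.data > cfg.structure_threshold).astype(np.float64)
            np.fill_diagonal(G_bin, 1.0)
            # straight-through: binary values forward, proximity gradient back
            A_st = P + Tensor(G_bin - P.data)
        else:
            A_st = Tensor(G_bin)

        E_sm = branch_sm.forward(S_t)
        E_st = branch_st.forward(A_st)
        loss_sm = bce_with_logits(E_sm @ E_sm.transpose(), S)
        loss_st = bce_with_logits(E_st @ E_st.transpose(), G_bin)
        loss = loss_sm + loss_st
        loss_fu = None
        if use_fusion:
            F = fusion.forward(E_sm, E_st, Tensor(e_km))
            loss_fu = bce_with_logits(F @ F.transpose(), S)
            loss = loss + loss_fu

        total = float(loss.data)
        if not np.isfinite(total):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: sm={float(loss_sm.data)}, "
                f"st={float(loss_st.data)}")
        rows.append({"epoch": epoch, "loss": total,
                     "loss_similarity": float(loss_sm.data),
                     "loss_structure": float(loss_st.data),
                     "loss_fusion": float(loss_fu.data) if loss_fu is not None else np.nan})
        for opt in opts:
            opt.zero_grad()
        loss.backward()
        if E_leaf is not None and E_leaf.grad is not None:
            encoder._drop_rng.bit_generator.state = rng_state
            encoder.backward_chunked(tokens, E_leaf.grad, train=drop_on)
        for opt in opts:
            opt.step()

        if total < best - 1e-9:
            best = total
            since_best = 0
        else:
            since_best += 1
            if since_best == cfg.patience:
                warnings.warn(f"loss has not improved for {cfg.patience} epochs")
        if verbose and epoch % 10 == 0:
            print(f"epoch {epoch:4d}  loss {total:.6f}")

    with no_grad():
        E_sm = branch_sm.forward(S_t).data
        E_st = branch_st.forward(Tensor(G_bin)).data
    return TrainingResult(e_sm=E_sm, e_st=E_st, structure_graph=G_bin,
                          log=pd.DataFrame(rows), fusion=fusion,
                          encoder=encoder, branches=(branch_sm, branch_st))
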