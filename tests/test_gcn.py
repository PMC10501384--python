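"""Graph convolution arithmetic, residual schedule and autoencoder training."""

import numpy as np
import pandas as pd
import pytest

from m6atmr.autodiff import Tensor
from m6atmr.gcn import (GcnConfig, SelfCorrelationGcn, alpha_schedule, gcn_layer,
                        reconstruction_loss, train)
from m6atmr.transformer import TransformerConfig

RNG = np.random.default_rng(17)


# -------------------------------------------------------------- alpha schedule
def test_alpha_schedule_values():
    assert alpha_schedule(0, 3) == pytest.approx(0.25)
    assert alpha_schedule(2, 3) == pytest.approx(0.75)
    assert alpha_schedule(0, 1) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        alpha_schedule(3, 3)


def test_alpha_schedule_sums_to_half_I():
    for I in (1, 2, 3, 5):
        total = sum(alpha_schedule(i, I) for i in range(I))
        assert total == pytest.approx(I * (I + 1) / (2 * (I + 1)))


# ------------------------------------------------------------------- gcn layer
def brute_gcn_layer(H, A, W):
    m = A.shape[0]
    Ahat = 0.5 * (A + A.T) + np.eye(m)
    deg = Ahat.sum(axis=1)
    Dinv = np.diag(1.0 / np.sqrt(deg))
    return np.maximum(Dinv @ Ahat @ Dinv @ H @ W, 0.0)


def test_gcn_layer_identity_adjacency():
    # A = I gives Ahat = 2I, whose normalization is exactly I
    H = np.eye(2)
    np.testing.assert_allclose(gcn_layer(H, np.eye(2), np.eye(2)), np.eye(2))


def test_gcn_layer_path_graph_hand_case():
    A = np.array([[0., 1., 0.], [1., 0., 1.], [0., 1., 0.]])
    H = np.ones((3, 2))
    W = np.ones((2, 2))
    np.testing.assert_allclose(gcn_layer(H, A, W), brute_gcn_layer(H, A, W),
                               atol=1e-12)


def test_gcn_layer_matches_bruteforce_random_instances():
    for _ in range(100):
        m, din, dout = RNG.integers(2, 7), RNG.integers(1, 6), RNG.integers(1, 6)
        A = RNG.uniform(size=(m, m))
        H = RNG.normal(size=(m, din))
        W = RNG.normal(size=(din, dout))
        got = gcn_layer(H, A, W)
        np.testing.assert_allclose(got, brute_gcn_layer(H, A, W), atol=1e-6)
        assert (got >= 0).all() and np.isfinite(got).all()


def test_gcn_layer_input_validation():
    with pytest.raises(ValueError):
        gcn_layer(np.ones((3, 2)), np.ones((2, 2)), np.ones((2, 2)))
    with pytest.raises(ValueError):
        gcn_layer(np.full((2, 2), np.nan), np.ones((2, 2)), np.ones((2, 2)))


# --------------------------------------------------------------- forward pass
def brute_selfcorr_forward(A, Er, weights, projections, I):
    """Straight-line unrolled oracle for the scaled-residual forward pass."""
    m = A.shape[0]
    Ahat = 0.5 * (A + A.T) + np.eye(m)
    deg = Ahat.sum(axis=1)
    N = np.diag(deg ** -0.5) @ Ahat @ np.diag(deg ** -0.5)
    H, R = Er, Er
    for i in range(I):
        Z = np.maximum(N @ H @ weights[i], 0.0)
        if projections[i] is not None:
            R = R @ projections[i]
        R = R + (i + 1) / (I + 1) * Z
        H = Z
    return R


def test_selfcorr_forward_matches_unrolled_oracle():
    m = 4
    cfg = GcnConfig(layers=3, hidden_dims=(3, 2, 2), seed=0)
    branch = SelfCorrelationGcn(m, cfg, np.random.default_rng(0))
    A = RNG.uniform(size=(m, m))
    got = branch.forward(Tensor(A)).data
    weights = [w.data for w in branch.weights]
    projs = [p.W.data if p is not None else None for p in branch.projections]
    expect = brute_selfcorr_forward(A, branch.Er.data, weights, projs, 3)
    np.testing.assert_allclose(got, expect, atol=1e-10)
    assert got.shape == (m, 2)


def test_selfcorr_forward_single_layer_unrolls_to_half_step():
    m = 3
    cfg = GcnConfig(layers=1, hidden_dims=(m,), seed=1)
    branch = SelfCorrelationGcn(m, cfg, np.random.default_rng(1))
    A = np.eye(m)
    Z = gcn_layer(branch.Er.data, A, branch.weights[0].data)
    expect = branch.Er.data + 0.5 * Z
    np.testing.assert_allclose(branch.forward(Tensor(A)).data, expect, atol=1e-12)


def test_selfcorr_forward_deterministic_and_adjacency_sensitive():
    cfg = GcnConfig(layers=2, hidden_dims=(4, 4), seed=3)
    Er = Tensor(np.full((5, 5), 0.3))
    b1 = SelfCorrelationGcn(5, cfg, np.random.default_rng(3), Er=Er)
    A1 = RNG.uniform(size=(5, 5))
    out_a = b1.forward(Tensor(A1)).data
    out_b = b1.forward(Tensor(A1)).data
    np.testing.assert_array_equal(out_a, out_b)
    # with identical (frozen) Er and weights, output depends on the adjacency
    A2 = RNG.uniform(size=(5, 5))
    assert not np.allclose(out_a, b1.forward(Tensor(A2)).data)


# -------------------------------------------------------- reconstruction loss
def brute_bce(hat, target, eps=1e-12):
    hat = np.clip(hat, eps, 1 - eps)
    total = 0.0
    for i in range(hat.shape[0]):
        for j in range(hat.shape[1]):
            total += -target[i, j] * np.log(hat[i, j]) \
                     - (1 - target[i, j]) * np.log(1 - hat[i, j])
    return total / hat.size


def test_reconstruction_loss_all_half_matrices():
    half = np.full((3, 3), 0.5)
    assert reconstruction_loss(half, half, half, half) == pytest.approx(2 * np.log(2))


def test_reconstruction_loss_perfect_limit_is_zero():
    target = (RNG.uniform(size=(4, 4)) > 0.5).astype(float)
    hat = np.clip(target, 1e-15, 1 - 1e-15)
    assert reconstruction_loss(hat, target, hat, target) == pytest.approx(0.0, abs=1e-10)


def test_reconstruction_loss_matches_double_loop_oracle():
    for _ in range(100):
        S_hat, G_hat = RNG.uniform(size=(3, 3)), RNG.uniform(size=(3, 3))
        S_t, G_t = RNG.uniform(size=(3, 3)), (RNG.uniform(size=(3, 3)) > 0.5).astype(float)
        got = reconstruction_loss(S_hat, S_t, G_hat, G_t)
        assert got == pytest.approx(brute_bce(S_hat, S_t) + brute_bce(G_hat, G_t),
                                    abs=1e-6)


def test_reconstruction_loss_rejects_bad_targets():
    ok = np.full((2, 2), 0.5)
    with pytest.raises(ValueError):
        reconstruction_loss(ok, ok * 3, ok, ok)


# ------------------------------------------------------------------- training
def _toy_training(m=24, L=10, epochs=12, seed=0, refresh_every=5, **kw):
    rng = np.random.default_rng(seed)
    S = rng.uniform(0.2, 0.8, size=(m, m))
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 1.0)
    tokens = rng.integers(0, 64, size=(m, L))
    cfg = GcnConfig(layers=2, hidden_dims=(12, 8), epochs=epochs,
                    refresh_every=refresh_every, seed=seed, learning_rate=1e-3,
                    train_fusion=False, **kw)
    tcfg = TransformerConfig(blocks=1, dropout=0.0, seed=seed)
    return train(S, tokens, cfg, tcfg)


def test_training_reduces_loss_and_yields_row_per_sequence():
    res = _toy_training()
    assert isinstance(res.log, pd.DataFrame)
    assert res.log.loss.iloc[-1] < res.log.loss.iloc[0]
    assert np.isfinite(res.log.loss).all()
    assert res.e_sm.shape[0] == 24 and res.e_st.shape[0] == 24
    assert set(np.unique(res.structure_graph)) <= {0.0, 1.0}


def test_training_static_graph_when_refresh_disabled():
    res = _toy_training(epochs=8, refresh_every=10 ** 9)
    # the graph is computed once and the structure loss target never changes
    assert res.log.loss_structure.notna().all()


def test_training_recovers_block_structure():
    """A two-cluster block-diagonal affinity is reproduced by the learned
    embeddings: within-block reconstructed similarity exceeds between-block."""
    m = 20
    S = np.full((m, m), 0.05)
    S[:10, :10] = 0.9
    S[10:, 10:] = 0.9
    np.fill_diagonal(S, 1.0)
    tokens = np.random.default_rng(0).integers(0, 64, size=(m, 8))
    cfg = GcnConfig(layers=2, hidden_dims=(16, 8), epochs=150, refresh_every=10 ** 9,
                    learning_rate=5e-3, seed=0, train_fusion=False)
    res = train(S, tokens, cfg, TransformerConfig(blocks=0, dropout=0.0, seed=0))
    E = res.e_sm
    rec = 1 / (1 + np.exp(-(E @ E.T)))
    within = np.concatenate([rec[:10, :10].ravel(), rec[10:, 10:].ravel()])
    between = rec[:10, 10:].ravel()
    assert within.mean() > between.mean()


def test_training_validates_inputs():
    with pytest.raises(ValueError):
        train(np.full((4, 4), 2.0), np.zeros((4, 6), dtype=int))  # S not in [0,1]
    with pytest.raises(ValueError):
        train(np.full((4, 4), 0.5), np.zeros((3, 6), dtype=int))  # m mismatch
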