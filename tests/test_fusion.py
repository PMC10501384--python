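"""Gated local-global fusion: convexity, gates, ablations, gradient flow."""

import numpy as np
import pytest

from m6atmr.autodiff import Tensor
from m6atmr.fusion import (ABLATION_MODES, FusionBlock, FusionPipeline,
                           fuse_branches, fuse_with_kmer, fusion_weight)

RNG = np.random.default_rng(23)


def _block(seed=0):
    return FusionBlock(np.random.default_rng(seed))


def test_fusion_weight_strictly_inside_unit_interval():
    for _ in range(20):
        w = fusion_weight(RNG.normal(size=(5, 12)), _block(1)).data
        assert (w > 0).all() and (w < 1).all()


def test_fusion_weight_zero_input_zero_block_gives_half():
    block = FusionBlock(None)  # zero-initialized stages are the zero map
    w = fusion_weight(np.zeros((3, 8)), block).data
    np.testing.assert_allclose(w, 0.5)


def test_fusion_weight_deterministic_and_rejects_nonfinite():
    x = RNG.normal(size=(4, 6))
    np.testing.assert_array_equal(fusion_weight(x, _block(3)).data,
                                  fusion_weight(x, _block(3)).data)
    with pytest.raises(ValueError):
        fusion_weight(np.full((2, 4), np.nan), _block(0))


def test_fuse_branches_equal_inputs_pass_through():
    v = RNG.normal(size=(6, 10))
    np.testing.assert_allclose(fuse_branches(v, v, _block(2)).data, v, atol=1e-12)


def test_fuse_branches_convexity_bounds():
    a, b = RNG.normal(size=(8, 16)), RNG.normal(size=(8, 16))
    out = fuse_branches(a, b, _block(4)).data
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    assert (out >= lo - 1e-12).all() and (out <= hi + 1e-12).all()


def test_fuse_branches_dimension_mismatch():
    with pytest.raises(ValueError):
        fuse_branches(np.zeros((2, 4)), np.zeros((2, 5)), _block(0))


def test_fuse_with_kmer_matches_straightline_oracle():
    """Frozen-parameter scalar re-computation of the whole gate arithmetic."""
    rng = np.random.default_rng(9)
    block = FusionBlock(rng)
    e_ss = RNG.normal(size=(5, 8))
    e_km = RNG.normal(size=(5, 8))

    def conv3(x, w, b):
        pad = np.pad(x, ((0, 0), (1, 1)))
        return w[0] * pad[:, :-2] + w[1] * pad[:, 1:-1] + w[2] * pad[:, 2:] + b

    def stage(x, s):
        y = conv3(x, s.w1.data, s.b1.data)
        mu, var = y.mean(0, keepdims=True), y.var(0, keepdims=True)
        y = (y - mu) / np.sqrt(var + 1e-5) * s.gamma.data + s.beta.data
        return conv3(np.maximum(y, 0.0), s.w2.data, s.b2.data)

    e_a = e_ss + e_km
    w = 1 / (1 + np.exp(-(stage(e_a, block.local)
                          + stage(e_a.mean(1, keepdims=True), block.global_))))
    expected = w * e_ss + (1 - w) * e_km
    got = fuse_with_kmer(e_ss, e_km, block).data
    np.testing.assert_allclose(got, expected, atol=1e-10)


def test_fusion_gradients_flow_end_to_end():
    """Finite-difference check through gate + convex combination on a toy."""
    block = _block(7)
    a = Tensor(RNG.normal(size=(2, 4)), requires_grad=True)
    b = Tensor(RNG.normal(size=(2, 4)), requires_grad=True)
    out = fuse_branches(a, b, block)
    (out * out).sum().backward()
    assert a.grad is not None and np.isfinite(a.grad).all()
    for p in block.parameters():
        assert p.grad is None or np.isfinite(p.grad).all()
    # numeric check on one conv weight
    w = block.local.w1
    eps = 1e-6
    base_data = w.data.copy()

    def value():
        out = fuse_branches(a.data, b.data, block)
        return float((out * out).sum().data)

    w.data = base_data + np.array([eps, 0, 0])
    hi = value()
    w.data = base_data - np.array([eps, 0, 0])
    lo = value()
    w.data = base_data
    for p in block.parameters():
        p.grad = None
    out2 = fuse_branches(a.data, b.data, block)
    (out2 * out2).sum().backward()
    assert w.grad[0] == pytest.approx((hi - lo) / (2 * eps), abs=1e-5)


# --------------------------------------------------------------- ablation API
def _pipeline_inputs(m=12, d=16, seed=0):
    rng = np.random.default_rng(seed)
    return (rng.normal(size=(m, d)), rng.normal(size=(m, d)),
            np.abs(rng.normal(size=(m, d))))


def _trained_pipeline(e_sm, e_st, e_km, steps=25):
    """Gates start neutral (exactly 1/2) by design, so train them briefly on
    the auxiliary reconstruction objective before exercising ablations."""
    from m6atmr.autodiff import Tensor, bce_with_logits
    from m6atmr.nn import Adam

    pipe = FusionPipeline(d_emb=e_sm.shape[1], d_km=e_km.shape[1], seed=1)
    target = np.clip(0.5 + 0.4 * np.sign(e_sm @ e_sm.T), 0, 1)
    opt = Adam(pipe.parameters(), lr=5e-2)
    for _ in range(steps):
        F = pipe.forward(Tensor(e_sm), Tensor(e_st), Tensor(e_km))
        loss = bce_with_logits(F @ F.transpose(), target)
        opt.zero_grad()
        loss.backward()
        opt.step()
    return pipe


def test_ablation_modes_distinct_and_row_counts():
    e_sm, e_st, e_km = _pipeline_inputs()
    pipe = _trained_pipeline(e_sm, e_st, e_km)
    mats = {mode: pipe.ablate(e_sm, e_st, e_km, mode=mode)
            for mode in ABLATION_MODES}
    for mode, F in mats.items():
        assert F.shape[0] == 12, mode
    keys = list(mats)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            assert not np.allclose(mats[keys[i]], mats[keys[j]]), \
                f"{keys[i]} aliases {keys[j]}"


def test_drop_raw_excludes_similarity_branch():
    pipe = FusionPipeline(d_emb=16, d_km=16, seed=2)
    e_sm, e_st, e_km = _pipeline_inputs(seed=3)
    other = np.random.default_rng(99).normal(size=e_sm.shape)
    base = pipe.ablate(e_sm, e_st, e_km, mode="drop-raw")
    perturbed = pipe.ablate(other, e_st, e_km, mode="drop-raw")
    np.testing.assert_allclose(base, perturbed, atol=1e-10)
    # and symmetrically for drop-trans
    base = pipe.ablate(e_sm, e_st, e_km, mode="drop-trans")
    perturbed = pipe.ablate(e_sm, other, e_km, mode="drop-trans")
    np.testing.assert_allclose(base, perturbed, atol=1e-10)


def test_weighted_only_equal_inputs_identity():
    pipe = FusionPipeline(d_emb=8, d_km=8, seed=0, standardize=False)
    v = RNG.normal(size=(5, 8))
    np.testing.assert_allclose(pipe.ablate(v, v, v, mode="weighted-only"), v,
                               atol=1e-12)


def test_unknown_mode_rejected():
    pipe = FusionPipeline(d_emb=8, d_km=8)
    with pytest.raises(ValueError):
        pipe.ablate(*_pipeline_inputs(m=4, d=8), mode="nope")
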