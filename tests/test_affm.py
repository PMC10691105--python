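"""Gated attention fusion: functional ops, masks, and the MHSA oracle."""

import numpy as np
import pytest

from pestfusion.affm import (AFFM, AttentionParams, GateMasks, GateParams,
                             attention_scores, gate_fusion, gate_masks,
                             head_output, project_qkv, selection_mask)
from pestfusion.autodiff import Tensor


def naive_mhsa(x, wq, wk, wv, d_k, eps=1e-5):
    """Independent textbook multi-head self-attention + batch-norm + residual,
    written with explicit loops."""
    n, d = x.shape
    heads = len(wq)
    head_outs = []
    for i in range(heads):
        q, k, v = x @ wq[i], x @ wk[i], x @ wv[i]
        s = np.zeros((n, n))
        for a in range(n):
            row = np.array([q[a] @ k[b] for b in range(n)]) / np.sqrt(d_k)
            row = np.exp(row - row.max())
            s[a] = row / row.sum()
        head_outs.append(s @ v)
    fused = np.concatenate(head_outs, axis=1)
    mu = fused.mean(axis=0)
    var = fused.var(axis=0)
    return (fused - mu) / np.sqrt(var + eps) + x


def make_params(n, d, h, rng):
    dh = d // h
    return AttentionParams([rng.normal(size=(d, dh)) for _ in range(h)],
                           [rng.normal(size=(d, dh)) for _ in range(h)],
                           [rng.normal(size=(d, dh)) for _ in range(h)],
                           d_k=d, d_v=d)


def make_gates(d, h, rng, scale=1.0):
    dh = d // h
    return GateParams(scale * rng.normal(size=(dh, dh)),
                      scale * rng.normal(size=(dh, dh)),
                      scale * rng.normal(size=dh), scale * rng.normal(size=dh),
                      scale * rng.normal(size=(2 * dh, dh)),
                      scale * rng.normal(size=(2 * dh, dh)),
                      scale * rng.normal(size=dh), scale * rng.normal(size=dh))


# -- functional ops -----------------------------------------------------------

def test_project_qkv_matches_triple_loop():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(3, 4))
    params = make_params(3, 4, 2, rng)
    q, k, v = project_qkv(x, params, head=1)
    for mat, w in ((q, params.wq[1]), (k, params.wk[1]), (v, params.wv[1])):
        ref = np.zeros_like(mat)
        for a in range(3):
            for j in range(2):
                for t in range(4):
                    ref[a, j] += x[a, t] * w[t, j]
        np.testing.assert_allclose(mat, ref, atol=1e-12)
    qz, kz, vz = project_qkv(np.zeros((3, 4)), params, head=0)
    assert not qz.any() and not kz.any() and not vz.any()


def test_gate_fusion_concatenation():
    rng = np.random.default_rng(1)
    q = rng.normal(size=(3, 4))
    k = rng.normal(size=(3, 4))
    eye = GateParams(np.eye(4), np.eye(4), np.zeros(4), np.zeros(4),
                     np.zeros((8, 4)), np.zeros((8, 4)),
                     np.zeros(4), np.zeros(4))
    np.testing.assert_allclose(gate_fusion(q, k, eye),
                               np.concatenate([q, k], axis=1))
    zero = GateParams(np.zeros((4, 4)), np.zeros((4, 4)), np.zeros(4),
                      np.zeros(4), np.zeros((8, 4)), np.zeros((8, 4)),
                      np.zeros(4), np.zeros(4))
    assert not gate_fusion(q, k, zero).any()


def test_gate_masks_sigmoid_behavior():
    rng = np.random.default_rng(2)
    g = rng.normal(size=(3, 8))
    zero = GateParams(np.eye(4), np.eye(4), np.zeros(4), np.zeros(4),
                      np.zeros((8, 4)), np.zeros((8, 4)),
                      np.zeros(4), np.zeros(4))
    masks = gate_masks(g, zero)
    np.testing.assert_allclose(masks.mq, 0.5)        # sigmoid(0) = 0.5
    np.testing.assert_allclose(masks.mk, 0.5)
    saturated = GateParams(np.eye(4), np.eye(4), np.zeros(4), np.zeros(4),
                           np.zeros((8, 4)), np.zeros((8, 4)),
                           np.full(4, 20.0), np.full(4, 20.0))
    m2 = gate_masks(g, saturated)
    np.testing.assert_allclose(m2.mq, 1.0, atol=1e-8)
    # random case vs scalar loops
    params = make_gates(8, 2, rng)
    m3 = gate_masks(g, params)
    for a in range(3):
        for j in range(4):
            z = sum(g[a, t] * params.wmq[t, j] for t in range(8)) \
                + params.bmq[j]
            assert m3.mq[a, j] == pytest.approx(1 / (1 + np.exp(-z)))
    assert ((m3.mq > 0) & (m3.mq < 1)).all()


def test_attention_scores_row_stochastic():
    rng = np.random.default_rng(3)
    q = rng.normal(size=(4, 6))
    k = rng.normal(size=(4, 6))
    masks = GateMasks(rng.uniform(0.1, 0.9, (4, 6)),
                      rng.uniform(0.1, 0.9, (4, 6)))
    s = attention_scores(q, k, masks, d_k=6)
    np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-12)
    # naive exp/sum oracle
    qm, km = masks.mq * q, masks.mk * k
    for a in range(4):
        row = np.array([qm[a] @ km[b] for b in range(4)]) / np.sqrt(6)
        row = np.exp(row)
        np.testing.assert_allclose(s[a], row / row.sum(), atol=1e-10)
    # zero queries -> uniform rows
    su = attention_scores(np.zeros((4, 6)), k, None, d_k=6)
    np.testing.assert_allclose(su, 0.25)
    s1 = attention_scores(np.ones((1, 6)), np.ones((1, 6)), None, d_k=6)
    np.testing.assert_allclose(s1, [[1.0]])


def test_selection_mask_thresholds():
    uniform = np.full((5, 5), 0.2)
    np.testing.assert_array_equal(selection_mask(uniform, 1 / 10).values, 1)
    s = np.array([[0.05, 0.95]])
    np.testing.assert_array_equal(selection_mask(s, 0.1).values, [[0, 1]])
    np.testing.assert_array_equal(selection_mask(s, 0.0).values, [[1, 1]])


def test_head_output_masking():
    rng = np.random.default_rng(4)
    s = attention_scores(rng.normal(size=(3, 4)), rng.normal(size=(3, 4)),
                        None, d_k=4)
    v = rng.normal(size=(3, 4))
    ones = selection_mask(s, 0.0)
    np.testing.assert_allclose(head_output(s, ones, v), s @ v)
    zeros = selection_mask(np.zeros((3, 3)) + s * 0, 1.0)
    assert not head_output(s, zeros, v).any()
    mask = selection_mask(s, 0.4)
    ref = np.zeros((3, 4))
    for a in range(3):
        for b in range(3):
            for f in range(4):
                ref[a, f] += mask.values[a, b] * s[a, b] * v[b, f]
    np.testing.assert_allclose(head_output(s, mask, v), ref, atol=1e-12)
    # after masking each row sum lies in [0, 1]
    masked = mask.values * s
    assert ((masked.sum(axis=1) >= 0) & (masked.sum(axis=1) <= 1 + 1e-12)).all()


# -- the trainable layer ------------------------------------------------------

def test_layer_matches_functional_composition():
    """The Tensor forward and the numpy functional ops are one algorithm."""
    rng = np.random.default_rng(5)
    layer = AFFM(d=8, heads=2, p=0.15, rng=np.random.default_rng(6))
    x = rng.normal(size=(4, 8))
    out = layer.forward(Tensor(x), training=False).data
    ap, gp = layer.attention_params(), layer.gate_params()
    head_outs = []
    for i in range(layer.heads):
        q, k, v = project_qkv(x, ap, i)
        masks = gate_masks(gate_fusion(q, k, gp), gp)
        s = attention_scores(q, k, masks, ap.d_k)
        mask = selection_mask(s, layer.p)
        head_outs.append(head_output(s, mask, v))
    fused = np.concatenate(head_outs, axis=1)
    bn = layer.bn   # inference path: running statistics
    ref = (fused - bn.running_mean) / np.sqrt(bn.running_var + bn.eps) \
        * bn.gamma.data + bn.beta.data + x
    np.testing.assert_allclose(out, ref, atol=1e-10)


@pytest.mark.parametrize("n,d,h", [(2, 8, 1), (5, 8, 2), (2, 16, 4),
                                   (5, 16, 4), (3, 8, 4)])
def test_pinned_gates_reduce_to_textbook_mhsa(n, d, h):
    rng = np.random.default_rng(1000 + n * d * h)
    layer = AFFM(d=d, heads=h, p=0.0, rng=rng)
    x = rng.normal(size=(n, d))
    out = layer.forward(Tensor(x), training=True, pin_gates=True).data
    ap = layer.attention_params()
    ref = naive_mhsa(x, ap.wq, ap.wk, ap.wv, ap.d_k)
    assert np.abs(out - ref).max() < 1e-5


def test_zero_value_projections_give_bn_shift_plus_x():
    layer = AFFM(d=8, heads=2, rng=np.random.default_rng(7))
    for w in layer._wv:
        w.data[...] = 0.0
    x = np.random.default_rng(8).normal(size=(4, 8))
    out = layer.forward(Tensor(x), training=False).data
    # BN of all-zero rows with fresh running stats is just beta (= 0)
    np.testing.assert_allclose(out, x, atol=1e-10)


def test_permutation_equivariance():
    rng = np.random.default_rng(9)
    layer = AFFM(d=8, heads=4, p=0.12, rng=np.random.default_rng(10))
    x = rng.normal(size=(5, 8))
    perm = rng.permutation(5)
    out = layer.forward(Tensor(x), training=False).data
    out_p = layer.forward(Tensor(x[perm]), training=False).data
    np.testing.assert_allclose(out_p, out[perm], atol=1e-10)


def test_selection_comparison_passes_no_gradient():
    layer = AFFM(d=8, heads=2, p=0.9, rng=np.random.default_rng(11))
    x = Tensor(np.random.default_rng(12).normal(size=(3, 8)),
               requires_grad=True)
    out = layer.forward(x, training=True)
    out.sum().backward()
    assert x.grad is not None and np.isfinite(x.grad).all()


def test_d_not_divisible_by_heads_rejected():
    with pytest.raises(ValueError, match="divisible"):
        AFFM(d=10, heads=4)
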