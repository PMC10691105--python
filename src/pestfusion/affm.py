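"""Adaptive filtering fusion: gated multi-head self-attention over a group.

A group of n same-class images yields an embedding matrix X (n x d).
Each attention head projects X to queries/keys/values, then two learned
filters restrict what flows through the attention:

* sigmoid **gate masks** M_Q, M_K — produced from a joint linear map of
  Q and K — multiplicatively damp query/key features before the scaled
  dot-product;
* a hard **selection mask** — any post-softmax attention score below a
  probability threshold p (default 1/(2 N_t)) is zeroed outright, with no
  renormalization, so embeddings the group considers irrelevant (label
  errors, target-absent frames) contribute nothing.

Head outputs are concatenated, batch-normalized over the group rows, and
added residually to X.  The selection comparison is a hard gate: no
gradient flows through the mask values themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .nn import BatchNorm1d, Module, softmax_rows

__all__ = ["AttentionParams", "GateParams", "GateMasks", "SelectionMask",
           "AFFM", "project_qkv", "gate_fusion", "gate_masks",
           "attention_scores", "selection_mask", "head_output"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class AttentionParams:
    """Per-head projection matrices; wq[i], wk[i]: (d, d_k/h), wv[i]: (d, d_v/h)."""

    wq: list[np.ndarray]
    wk: list[np.ndarray]
    wv: list[np.ndarray]
    d_k: int
    d_v: int

    @property
    def heads(self) -> int:
        return len(self.wq)


@dataclass
class GateParams:
    wgq: np.ndarray   # (d/h, d/h)
    wgk: np.ndarray   # (d/h, d/h)
    bgq: np.ndarray   # (d/h,)
    bgk: np.ndarray   # (d/h,)
    wmq: np.ndarray   # (2d/h, d/h)
    wmk: np.ndarray   # (2d/h, d/h)
    bmq: np.ndarray   # (d/h,)
    bmk: np.ndarray   # (d/h,)


@dataclass
class GateMasks:
    mq: np.ndarray
    mk: np.ndarray

    def __post_init__(self):
        for m in (self.mq, self.mk):
            if not ((m > 0.0) & (m < 1.0)).all():
                raise ValueError("gate masks must lie strictly in (0, 1)")


@dataclass
class SelectionMask:
    values: np.ndarray
    p: float

    def __post_init__(self):
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("selection mask must be binary")
        self.values = self.values.astype(np.uint8)


def project_qkv(x: np.ndarray, params: AttentionParams,
                head: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear projections Q = X Wq, K = X Wk, V = X Wv for one head."""
    return x @ params.wq[head], x @ params.wk[head], x @ params.wv[head]


def gate_fusion(q: np.ndarray, k: np.ndarray, params: GateParams) -> np.ndarray:
    """Map Q, K to a joint space and concatenate: G = [Q Wgq + b | K Wgk + b]."""
    if q.shape != k.shape:
        raise ValueError("Q and K must share shape")
    return np.concatenate([q @ params.wgq + params.bgq,
                           k @ params.wgk + params.bgk], axis=1)


def gate_masks(g: np.ndarray, params: GateParams) -> GateMasks:
    """Two parallel FC layers + sigmoid give the query and key masks."""
    return GateMasks(_sigmoid(g @ params.wmq + params.bmq),
                     _sigmoid(g @ params.wmk + params.bmk))


def attention_scores(q: np.ndarray, k: np.ndarray, masks: GateMasks | None,
                     d_k: int) -> np.ndarray:
    """Row-softmax of the gated scaled dot-product; rows sum to 1."""
    if masks is not None:
        q = masks.mq * q
        k = masks.mk * k
    z = (q @ k.T) / np.sqrt(d_k)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def selection_mask(s: np.ndarray, p: float) -> SelectionMask:
    """Zero every attention score strictly below probability p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    return SelectionMask((s >= p).astype(np.uint8), p)


def head_output(s: np.ndarray, mask: SelectionMask | None,
                v: np.ndarray) -> np.ndarray:
    """h = (mask . S) V; masked rows are NOT renormalized."""
    if mask is not None:
        s = mask.values * s
    return s @ v


class AFFM(Module):
    """Trainable fusion layer; forward follows the functional ops exactly.

    Ablation switches: `qk_mask` / `v_mask` toggle the sigmoid gates and
    the hard selection mask independently; `pin_gates` is a test hook
    equivalent to both gates off, reducing the layer to textbook
    multi-head self-attention + BN + residual.
    """

    def __init__(self, d: int, heads: int = 4, p: float = 0.1,
                 qk_mask: bool = True, v_mask: bool = True,
                 rng: np.random.Generator | None = None):
        if d % heads != 0:
            raise ValueError(f"d={d} not divisible by heads={heads}")
        rng = rng or np.random.default_rng()
        self.d, self.heads, self.p = d, heads, p
        self.qk_mask, self.v_mask = qk_mask, v_mask
        self.d_k = self.d_v = d          # scale uses sqrt(d_k) with d_k = d
        dh = d // heads

        def init(*shape):
            bound = np.sqrt(6.0 / (shape[0] + shape[-1]))
            return Tensor(rng.uniform(-bound, bound, shape), requires_grad=True)

        self._wq = [init(d, dh) for _ in range(heads)]
        self._wk = [init(d, dh) for _ in range(heads)]
        self._wv = [init(d, dh) for _ in range(heads)]
        self._wgq = init(dh, dh)
        self._wgk = init(dh, dh)
        self._bgq = Tensor(np.zeros(dh), requires_grad=True)
        self._bgk = Tensor(np.zeros(dh), requires_grad=True)
        self._wmq = init(2 * dh, dh)
        self._wmk = init(2 * dh, dh)
        self._bmq = Tensor(np.zeros(dh), requires_grad=True)
        self._bmk = Tensor(np.zeros(dh), requires_grad=True)
        self.bn = BatchNorm1d(d)

    # checkpoint naming: head{i}.{WQ,WK,WV}, gate.*, bn.*
    def parameters(self):
        for i in range(self.heads):
            yield f"head{i}.WQ", self._wq[i]
            yield f"head{i}.WK", self._wk[i]
            yield f"head{i}.WV", self._wv[i]
        for name, t in (("WGQ", self._wgq), ("WGK", self._wgk),
                        ("bGQ", self._bgq), ("bGK", self._bgk),
                        ("WMQ", self._wmq), ("WMK", self._wmk),
                        ("bMQ", self._bmq), ("bMK", self._bmk)):
            yield f"gate.{name}", t
        yield "bn.gamma", self.bn.gamma
        yield "bn.beta", self.bn.beta

    def buffers(self):
        yield "bn.running_mean", self.bn.running_mean
        yield "bn.running_var", self.bn.running_var

    def attention_params(self) -> AttentionParams:
        return AttentionParams([w.data for w in self._wq],
                               [w.data for w in self._wk],
                               [w.data for w in self._wv],
                               d_k=self.d_k, d_v=self.d_v)

    def gate_params(self) -> GateParams:
        return GateParams(self._wgq.data, self._wgk.data, self._bgq.data,
                          self._bgk.data, self._wmq.data, self._wmk.data,
                          self._bmq.data, self._bmk.data)

    def _fuse(self, x: Tensor, pin_gates: bool, p: float) -> Tensor:
        """Gated attention within one group; concatenated heads, pre-BN."""
        head_outs = []
        for i in range(self.heads):
            q = x @ self._wq[i]
            k = x @ self._wk[i]
            v = x @ self._wv[i]
            if self.qk_mask and not pin_gates:
                g = concat([q @ self._wgq + self._bgq,
                            k @ self._wgk + self._bgk], axis=1)
                mq = (g @ self._wmq + self._bmq).sigmoid()
                mk = (g @ self._wmk + self._bmk).sigmoid()
                q = mq * q
                k = mk * k
            s = softmax_rows((q @ k.T) * (1.0 / np.sqrt(self.d_k)))
            if self.v_mask and not pin_gates and p > 0.0:
                hard = (s.data >= p).astype(np.float64)   # constant: no grad
                s = s * hard
            head_outs.append(s @ v)
        return head_outs[0] if len(head_outs) == 1 else concat(head_outs, axis=1)

    def forward(self, x: Tensor, training: bool = False,
                pin_gates: bool = False, p: float | None = None) -> Tensor:
        p = self.p if p is None else p
        fused = self._fuse(x, pin_gates, p)
        return self.bn.forward(fused, training=training) + x

    def forward_groups(self, xs: list[Tensor], training: bool = True,
                       p: float | None = None) -> list[Tensor]:
        """Fuse several groups; attention stays within each group but BN
        normalizes over all rows of the batch, so the statistics mix
        classes the way an ordinary training batch does."""
        p = self.p if p is None else p
        fused = [self._fuse(x, False, p) for x in xs]
        stacked = fused[0] if len(fused) == 1 else concat(fused, axis=0)
        normed = self.bn.forward(stacked, training=training)
        outs = []
        offset = 0
        for x in xs:
            n = x.shape[0]
            outs.append(normed[offset:offset + n] + x)
            offset += n
        return outs
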