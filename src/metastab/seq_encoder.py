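"""Attention-BiGRU sequence encoder.

The token-embedding matrix Z (m x d1) of a molecule is passed through a
bidirectional GRU; each position's hidden state h_t is the concatenation of
the forward state at t and the backward state at t (d2 = 2 x per-direction
hidden size, 200 under defaults).  A multihead additive-attention pool then
turns the m hidden states into a single molecule vector: per head, raw
scores are a tanh feed-forward map of H projected onto a context vector,
normalized with a softmax over atoms; the attention-weighted sums are
averaged across heads and mapped through a fully connected layer (ReLU) to
the sequence representation s_i.

Batches are padded to the longest molecule; masked positions are excluded
from both the recurrence (their states carry the last valid state forward)
and the attention softmax.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .nn import Linear, Module, Parameter, Tensor, concat
from .nn.layers import glorot_uniform

__all__ = ["GRU", "BiGRU", "AttentionPool", "SequenceEncoder",
           "SequenceEncoderOutput", "bigru_encode", "attention_pool",
           "masked_softmax", "pad_batch"]


def pad_batch(matrices: Sequence[np.ndarray]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad a list of m_i x d matrices to (B, T, d); returns (X, mask, lengths)."""
    lengths = np.array([m.shape[0] for m in matrices], dtype=np.int64)
    T = int(lengths.max())
    d = matrices[0].shape[1]
    X = np.zeros((len(matrices), T, d), dtype=matrices[0].dtype)
    mask = np.zeros((len(matrices), T), dtype=matrices[0].dtype)
    for i, m in enumerate(matrices):
        X[i, :m.shape[0]] = m
        mask[i, :m.shape[0]] = 1.0
    return X, mask, lengths


class GRU(Module):
    """Single-direction GRU over a padded batch (batch-first).

    Gate equations (r = reset, z = update, n = candidate):
        r_t = sigmoid(x_t W_ir + h_{t-1} W_hr + b_ir + b_hr)
        z_t = sigmoid(x_t W_iz + h_{t-1} W_hz + b_iz + b_hz)
        n_t = tanh(x_t W_in + b_in + r_t * (h_{t-1} W_hn + b_hn))
        h_t = (1 - z_t) * n_t + z_t * h_{t-1}
    """

    def __init__(self, input_size: int, hidden_size: int, rng):
        super().__init__()
        self.input_size = input_size
        self.hidden_size = hidden_size
        h = hidden_size
        a = 1.0 / np.sqrt(h)
        self.w_ih = Parameter(rng.uniform(-a, a, (input_size, 3 * h)).astype(np.float32))
        self.w_hh = Parameter(rng.uniform(-a, a, (h, 3 * h)).astype(np.float32))
        self.b_ih = Parameter(np.zeros(3 * h, dtype=np.float32))
        self.b_hh = Parameter(np.zeros(3 * h, dtype=np.float32))

    def forward(self, X: Tensor, mask: np.ndarray) -> Tensor:
        """X: (B, T, input_size); mask: (B, T) 1/0. Returns (B, T, hidden)."""
        return _gru_fused(X, mask, self.w_ih, self.w_hh, self.b_ih, self.b_hh,
                          self.hidden_size)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _gru_fused(X: Tensor, mask: np.ndarray, w_ih, w_hh, b_ih, b_hh,
               h_size: int) -> Tensor:
    """Whole GRU recurrence as one tape node with a hand-written backward.

    The per-timestep gate algebra runs in plain numpy (saving thousands of
    tiny tape nodes per batch); gradients for X and the four weight tensors
    are accumulated in a single reverse sweep.
    """
    B, T, d = X.shape
    h = h_size
    dtype = X.data.dtype
    Xp = (X.data.reshape(B * T, d) @ w_ih.data + b_ih.data).reshape(B, T, 3 * h)
    state = np.zeros((B, h), dtype=dtype)
    out = np.empty((B, T, h), dtype=dtype)
    rs = np.empty((B, T, h), dtype=dtype)
    zs = np.empty((B, T, h), dtype=dtype)
    ns = np.empty((B, T, h), dtype=dtype)
    ghn = np.empty((B, T, h), dtype=dtype)
    prev = np.empty((B, T, h), dtype=dtype)
    for t in range(T):
        prev[:, t] = state
        gh = state @ w_hh.data + b_hh.data
        gx = Xp[:, t]
        r = _sigmoid(gx[:, :h] + gh[:, :h])
        z = _sigmoid(gx[:, h:2 * h] + gh[:, h:2 * h])
        n = np.tanh(gx[:, 2 * h:] + r * gh[:, 2 * h:])
        h_mid = (1.0 - z) * n + z * state
        m = mask[:, t:t + 1]
        state = h_mid * m + state * (1.0 - m)
        out[:, t] = state
        rs[:, t], zs[:, t], ns[:, t], ghn[:, t] = r, z, n, gh[:, 2 * h:]

    def backward(g):
        w_hh_t = w_hh.data.T
        dW_hh = np.zeros_like(w_hh.data)
        db_hh = np.zeros_like(b_hh.data)
        dXp = np.empty((B, T, 3 * h), dtype=dtype)
        dh = np.zeros((B, h), dtype=dtype)
        need_whh = w_hh.requires_grad
        for t in range(T - 1, -1, -1):
            dh = dh + g[:, t]
            m = mask[:, t:t + 1]
            r, z, n = rs[:, t], zs[:, t], ns[:, t]
            hp = prev[:, t]
            dh_mid = dh * m
            dh_prev = dh * (1.0 - m)
            dn = dh_mid * (1.0 - z)
            dz = dh_mid * (hp - n)
            dh_prev += dh_mid * z
            dan = dn * (1.0 - n * n)
            dr = dan * ghn[:, t]
            dghn = dan * r
            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            dgh = np.concatenate([dar, daz, dghn], axis=1)
            dh_prev += dgh @ w_hh_t
            if need_whh:
                dW_hh += hp.T @ dgh
                db_hh += dgh.sum(axis=0)
            dXp[:, t, :h] = dar
            dXp[:, t, h:2 * h] = daz
            dXp[:, t, 2 * h:] = dan
            dh = dh_prev
        flatXp = dXp.reshape(B * T, 3 * h)
        if need_whh:
            w_hh._acc(dW_hh)
            b_hh._acc(db_hh)
        if w_ih.requires_grad:
            w_ih._acc(X.data.reshape(B * T, d).T @ flatXp)
            b_ih._acc(flatXp.sum(axis=0))
        if X.requires_grad:
            X._acc((flatXp @ w_ih.data.T).reshape(B, T, d))

    return Tensor._make(out, (X, w_ih, w_hh, b_ih, b_hh), backward)


def _reverse_indices(lengths: np.ndarray, T: int) -> np.ndarray:
    """Per-row time indices that reverse each sequence within its length."""
    idx = np.tile(np.arange(T), (len(lengths), 1))
    for b, L in enumerate(lengths):
        idx[b, :L] = np.arange(L - 1, -1, -1)
    return idx


class BiGRU(Module):
    """Bidirectional GRU: one forward and one backward recurrence, concatenated."""

    def __init__(self, input_size: int, hidden_size: int, rng):
        super().__init__()
        self.fwd = GRU(input_size, hidden_size, rng)
        self.bwd = GRU(input_size, hidden_size, rng)
        self.output_size = 2 * hidden_size

    def forward(self, X: Tensor, mask: np.ndarray, lengths: np.ndarray) -> Tensor:
        B, T, _ = X.shape
        rows = np.arange(B)[:, None]
        rev = _reverse_indices(lengths, T)
        Hf = self.fwd(X, mask)
        Xr = X[rows, rev]
        Hb_rev = self.bwd(Xr, mask)
        Hb = Hb_rev[rows, rev]
        return concat([Hf, Hb], axis=2)


def masked_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Softmax over axis 1 restricted to mask==1 positions."""
    shift = np.where(mask > 0, scores.data, -np.inf).max(axis=1, keepdims=True)
    e = (scores - shift).exp() * mask
    return e / e.sum(axis=1, keepdims=True)


class AttentionPool(Module):
    """Multihead additive attention over atom positions + FC to s_i.

    Each head scores atoms with v_k^T tanh(W_k h_t + b_k); softmax over
    atoms yields a distribution on the simplex.  Head contexts are averaged
    and passed through a ReLU fully connected layer.
    """

    def __init__(self, d2: int, d_s: int, heads: int = 4, att_dim: int = 100,
                 rng=None):
        super().__init__()
        if heads < 1:
            raise ValueError("heads must be >= 1")
        self.heads = heads
        self.att_dim = att_dim
        self.score_w = [Parameter(glorot_uniform(rng, d2, att_dim)) for _ in range(heads)]
        self.score_b = [Parameter(np.zeros(att_dim, dtype=np.float32)) for _ in range(heads)]
        self.score_v = [Parameter(glorot_uniform(rng, att_dim, 1)) for _ in range(heads)]
        self.fc = Linear(d2, d_s, rng)

    def forward(self, H: Tensor, mask: np.ndarray) -> Tuple[List[Tensor], Tensor]:
        B, T, d2 = H.shape
        flat = H.reshape(B * T, d2)
        alphas, contexts = [], []
        for w, b, v in zip(self.score_w, self.score_b, self.score_v):
            raw = ((flat @ w + b).tanh() @ v).reshape(B, T)
            alpha = masked_softmax(raw, mask)
            alphas.append(alpha)
            contexts.append((alpha.reshape(B, T, 1) * H).sum(axis=1))
        ctx = contexts[0]
        for c in contexts[1:]:
            ctx = ctx + c
        ctx = ctx * (1.0 / self.heads)
        s = self.fc(ctx).relu()
        return alphas, s


@dataclass
class SequenceEncoderOutput:
    hidden: np.ndarray            # m x d2
    attention: List[np.ndarray]   # per head, length-m simplex vectors
    seq_rep: np.ndarray           # d_s


class SequenceEncoder(Module):
    """BiGRU + multihead attention pooling, mapping Z (m x d1) to s_i."""

    def __init__(self, d1: int = 100, d2: int = 200, d_s: int = 256,
                 heads: int = 4, att_dim: int = 100, rng=None):
        super().__init__()
        if d2 % 2:
            raise ValueError("d2 must be even (two directions)")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.bigru = BiGRU(d1, d2 // 2, rng)
        self.pool = AttentionPool(d2, d_s, heads=heads, att_dim=att_dim, rng=rng)

    def forward(self, X: Tensor, mask: np.ndarray, lengths: np.ndarray):
        H = self.bigru(X, mask, lengths)
        alphas, s = self.pool(H, mask)
        return H, alphas, s

    def encode_one(self, Z: np.ndarray) -> SequenceEncoderOutput:
        """Convenience single-molecule forward (no gradients)."""
        from .nn import no_grad
        with no_grad():
            X, mask, lengths = pad_batch([Z])
            H, alphas, s = self.forward(Tensor(X), mask, lengths)
        return SequenceEncoderOutput(
            hidden=H.data[0], attention=[a.data[0] for a in alphas],
            seq_rep=s.data[0])


# -- functional wrappers (single molecule, numpy in / numpy out) -----------

def bigru_encode(Z: np.ndarray, bigru: BiGRU) -> np.ndarray:
    """Run one molecule's embedding matrix (m x d1) through a BiGRU -> m x d2."""
    if Z.ndim != 2 or Z.shape[0] < 1:
        raise ValueError("Z must be a non-empty m x d1 matrix")
    if Z.shape[1] != bigru.fwd.input_size:
        raise ValueError(f"dimension mismatch: Z has d1={Z.shape[1]}, "
                         f"encoder expects {bigru.fwd.input_size}")
    from .nn import no_grad
    with no_grad():
        X, mask, lengths = pad_batch([Z])
        H = bigru(Tensor(X), mask, lengths)
    return H.data[0]


def attention_pool(H: np.ndarray, pool: AttentionPool) -> Tuple[List[np.ndarray], np.ndarray]:
    """Pool one molecule's hidden matrix (m x d2); returns (per-head weights, s_i)."""
    from .nn import no_grad
    with no_grad():
        X, mask, _ = pad_batch([H])
        alphas, s = pool(Tensor(X), mask)
    return [a.data[0] for a in alphas], s.data[0]
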