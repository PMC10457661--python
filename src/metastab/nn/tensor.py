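"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a numpy array and records the operations applied to
it on a tape; :meth:`Tensor.backward` walks the tape in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``.  Only the operations needed by the encoders in this
package are implemented (broadcast arithmetic, matmul, pointwise
nonlinearities, reductions, indexing/gather, concatenation/stacking and
segment scatter reductions for batched graphs).

Floating dtype is preserved: float32 inputs stay float32 (the training
default), float64 inputs stay float64 (useful for oracle comparisons).
"""

from __future__ import annotations

import contextlib

import numpy as np

DEFAULT_DTYPE = np.float32

# global switch used by no_grad(); when False no tape is recorded
_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling tape recording (evaluation mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _as_array(x):
    if isinstance(x, np.ndarray):
        if x.dtype in (np.float32, np.float64):
            return x
        return x.astype(DEFAULT_DTYPE)
    if isinstance(x, (int, float)):
        # weak-typed scalars: keep float32 graphs in float32 (numpy still
        # promotes float32-scalar op float64-array to float64)
        return np.asarray(x, dtype=DEFAULT_DTYPE)
    arr = np.asarray(x)
    if arr.dtype in (np.float32, np.float64):
        return arr
    return arr.astype(DEFAULT_DTYPE)


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == tuple(shape):
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _is_fancy(key):
    if isinstance(key, tuple):
        return any(isinstance(k, (np.ndarray, list)) for k in key)
    return isinstance(key, (np.ndarray, list))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad=False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._prev = ()
        self._backward = None

    # -- construction of tape nodes -------------------------------------
    @classmethod
    def _make(cls, data, prev, backward):
        out = cls.__new__(cls)
        out.data = data
        out.grad = None
        if _grad_enabled and any(p.requires_grad for p in prev):
            out.requires_grad = True
            out._prev = tuple(prev)
            out._backward = backward
        else:
            out.requires_grad = False
            out._prev = ()
            out._backward = None
        return out

    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def _acc(self, g):
        if self.requires_grad:
            g = _unbroadcast(np.asarray(g, dtype=self.data.dtype), self.data.shape)
            if self.grad is None:
                # keep a reference; accumulation below is out-of-place, and no
                # backward closure mutates the arrays it hands out
                self.grad = g
            else:
                self.grad = self.grad + g

    # -- basic properties ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self):
        return self.data

    def detach(self):
        return Tensor(self.data)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            self._acc(g)
            other._acc(g)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            self._acc(g * other.data)
            other._acc(g * self.data)

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(g):
            self._acc(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = self._lift(other)
        out_data = self.data - other.data

        def backward(g):
            self._acc(g)
            other._acc(-g)

        return Tensor._make(out_data, (self, other), backward)

    def __rsub__(self, other):
        return self._lift(other).__sub__(self)

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            self._acc(g / other.data)
            other._acc(-g * self.data / (other.data * other.data))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other).__truediv__(self)

    def __pow__(self, p):
        assert np.isscalar(p)
        out_data = self.data ** p

        def backward(g):
            self._acc(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            self._acc(g @ other.data.T)
            other._acc(self.data.T @ g)

        return Tensor._make(out_data, (self, other), backward)

    # -- pointwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._acc(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._acc(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._acc(g * (1.0 - out_data * out_data))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        # numerically stable logistic
        out_data = np.empty_like(self.data)
        pos = self.data >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ex = np.exp(self.data[~pos])
        out_data[~pos] = ex / (1.0 + ex)

        def backward(g):
            self._acc(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0).astype(self.data.dtype)

        def backward(g):
            self._acc(g * mask)

        return Tensor._make(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            self._acc(g * sign)

        return Tensor._make(np.abs(self.data), (self,), backward)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._acc(np.broadcast_to(g, self.data.shape))

        return Tensor._make(np.asarray(out_data), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        expanded = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == expanded)
        counts = mask.sum(axis=axis, keepdims=True)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._acc(np.broadcast_to(g, self.data.shape) * mask / counts)

        return Tensor._make(np.asarray(out_data), (self,), backward)

    # -- shaping ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.data.shape

        def backward(g):
            self._acc(g.reshape(old_shape))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    @property
    def T(self):
        def backward(g):
            self._acc(g.T)

        return Tensor._make(self.data.T, (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]
        fancy = _is_fancy(key)

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if fancy:
                    np.add.at(full, key, g)
                else:
                    full[key] += g
                self._acc(full)

        return Tensor._make(np.ascontiguousarray(out_data), (self,), backward)

    # -- autodiff --------------------------------------------------------
    def backward(self, grad=None):
        if not self.requires_grad:
            raise RuntimeError("called backward() on a tensor that does not require grad")
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological sort over the tape
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


# -- free functions -------------------------------------------------------

def concat(tensors, axis=0):
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            t._acc(g[tuple(idx)])

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors, axis=0):
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            t._acc(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def _contiguous_offsets(segment_ids, num_segments):
    """Row offsets if segment_ids is sorted 0..num_segments-1 with no gaps."""
    if len(segment_ids) == 0:
        return None
    counts = np.bincount(segment_ids, minlength=num_segments)
    if np.any(counts == 0):
        return None
    expected = np.repeat(np.arange(num_segments), counts)
    if expected.shape != segment_ids.shape or not np.array_equal(expected, segment_ids):
        return None
    return np.concatenate([[0], np.cumsum(counts)[:-1]])


def segment_sum(x, segment_ids, num_segments):
    """Sum rows of ``x`` (n x d) into ``num_segments`` buckets."""
    x = Tensor._lift(x)
    offsets = _contiguous_offsets(segment_ids, num_segments)
    if offsets is not None:
        out_data = np.add.reduceat(x.data, offsets, axis=0)
    else:
        out_data = np.zeros((num_segments,) + x.data.shape[1:], dtype=x.data.dtype)
        np.add.at(out_data, segment_ids, x.data)

    def backward(g):
        x._acc(g[segment_ids])

    return Tensor._make(out_data, (x,), backward)


def segment_mean(x, segment_ids, num_segments):
    x = Tensor._lift(x)
    counts = np.bincount(segment_ids, minlength=num_segments).astype(x.data.dtype)
    counts = np.maximum(counts, 1.0)[:, None]
    return segment_sum(x, segment_ids, num_segments) / Tensor(counts)


def segment_max(x, segment_ids, num_segments):
    x = Tensor._lift(x)
    offsets = _contiguous_offsets(segment_ids, num_segments)
    if offsets is not None:
        out_data = np.maximum.reduceat(x.data, offsets, axis=0)
        mask = (x.data == out_data[segment_ids])
        counts = np.add.reduceat(mask.astype(x.data.dtype), offsets, axis=0)
    else:
        out_data = np.full((num_segments,) + x.data.shape[1:], -np.inf, dtype=x.data.dtype)
        np.maximum.at(out_data, segment_ids, x.data)
        mask = (x.data == out_data[segment_ids])
        counts = np.zeros_like(out_data)
        np.add.at(counts, segment_ids, mask.astype(x.data.dtype))
    counts = np.maximum(counts, 1.0)

    def backward(g):
        x._acc(g[segment_ids] * mask / counts[segment_ids])

    return Tensor._make(out_data, (x,), backward)


def spmm(A, x):
    """Sparse-dense product A @ x for a scipy sparse matrix A (constant)."""
    x = Tensor._lift(x)
    At = A.T.tocsr()

    def backward(g):
        x._acc(At @ g)

    return Tensor._make(A @ x.data, (x,), backward)


def bce_with_logits_sum(logits, targets):
    """Summed binary cross-entropy on logits (one primitive, exact gradient).

    forward: sum over i of softplus(l_i) - y_i * l_i
    backward: sigmoid(l_i) - y_i
    """
    logits = Tensor._lift(logits)
    l = logits.data
    y = np.asarray(targets, dtype=l.dtype)
    sp = np.maximum(l, 0.0) + np.log1p(np.exp(-np.abs(l)))
    out_data = np.asarray((sp - y * l).sum())
    sig = np.empty_like(l)
    pos = l >= 0
    sig[pos] = 1.0 / (1.0 + np.exp(-l[pos]))
    ex = np.exp(l[~pos])
    sig[~pos] = ex / (1.0 + ex)

    def backward(g):
        logits._acc(g * (sig - y))

    return Tensor._make(out_data, (logits,), backward)
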