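"""Neural-network building blocks on top of :mod:`metastab.nn.tensor`."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Parameter):
                        params.append(item)
                    elif isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def train(self, mode=True):
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def astype(self, dtype):
        """Cast all parameters (and buffers) in place; returns self."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.astype(dtype)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.astype(dtype)
        if hasattr(self, "running_mean"):
            self.running_mean = self.running_mean.astype(dtype)
            self.running_var = self.running_var.astype(dtype)
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def glorot_uniform(rng, fan_in, fan_out, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features, out_features, rng, bias=True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(glorot_uniform(rng, in_features, out_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm1d(Module):
    """Batch normalization over axis 0 with running statistics.

    Falls back to running statistics when batch statistics are undefined
    (a single row in training mode) and always uses them in eval mode.
    """

    def __init__(self, num_features, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features, dtype=np.float32))
        self.beta = Parameter(np.zeros(num_features, dtype=np.float32))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x):
        if self.training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            n = x.shape[0]
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel()).astype(self.running_mean.dtype)
            unbiased = var.data.ravel() * n / max(n - 1, 1)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased).astype(self.running_var.dtype)
            inv = (var + self.eps) ** -0.5
            return self.gamma * (xc * inv) + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.gamma * ((x - self.running_mean) * inv) + self.beta


class MLP(Module):
    """Stack of Linear layers with ReLU (and optional batch-norm) between.

    The hidden-layer pattern is linear -> [batch-norm ->] relu; the final
    linear layer has no activation unless ``final_activation`` is set.
    """

    def __init__(self, dims, rng, batch_norm=False, final_activation=False):
        super().__init__()
        self.layers = []  # sequence of ("linear"|"bn"|"relu", module-or-None)
        n = len(dims) - 1
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            self.layers.append(("linear", Linear(a, b, rng)))
            if i < n - 1 or final_activation:
                if batch_norm:
                    self.layers.append(("bn", BatchNorm1d(b)))
                self.layers.append(("relu", None))
        self.dims = tuple(dims)

    def parameters(self):
        params = []
        for _, mod in self.layers:
            if mod is not None:
                params.extend(mod.parameters())
        return params

    def train(self, mode=True):
        self.training = mode
        for _, mod in self.layers:
            if mod is not None:
                mod.train(mode)
        return self

    def astype(self, dtype):
        for _, mod in self.layers:
            if mod is not None:
                mod.astype(dtype)
        return self

    def forward(self, x):
        for kind, mod in self.layers:
            x = mod(x) if mod is not None else x.relu()
        return x
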