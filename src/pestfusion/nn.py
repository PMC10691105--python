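"""Neural-network layers and the SGD optimizer used by the pipeline.

Layers follow a minimal Module protocol: ``parameters()`` yields
``(name, Tensor)`` pairs and ``forward`` builds the autodiff graph.
Weight initialization is He-uniform for convolutions and Glorot-uniform
for linear maps, drawn from an explicit ``numpy.random.Generator`` so
runs are reproducible from a single seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor, conv2d

__all__ = ["Module", "Conv2d", "Linear", "BatchNorm1d", "Dropout", "SGD",
           "log_softmax", "softmax_rows"]


class Module:
    def parameters(self) -> Iterator[tuple[str, Tensor]]:
        for key, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield key, val
            elif isinstance(val, Module):
                for sub, p in val.parameters():
                    yield f"{key}.{sub}", p
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, p in item.parameters():
                            yield f"{key}{i}.{sub}", p

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All learnable parameters plus persistent buffers, by name."""
        out = {name: p.data for name, p in self.parameters()}
        for name, buf in self.buffers():
            out[name] = buf
        return out

    def buffers(self) -> Iterator[tuple[str, np.ndarray]]:
        for key, val in vars(self).items():
            if isinstance(val, Module):
                for sub, b in val.buffers():
                    yield f"{key}.{sub}", b
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, b in item.buffers():
                            yield f"{key}{i}.{sub}", b

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        own = {name: p for name, p in self.parameters()}
        bufs = dict(self.buffers())
        for name, arr in arrays.items():
            if name in own:
                own[name].data[...] = arr
            elif name in bufs:
                bufs[name][...] = arr


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel * kernel
        bound = np.sqrt(6.0 / fan_in)
        self.weight = Tensor(rng.uniform(-bound, bound,
                                         (c_out, c_in, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        bound = np.sqrt(6.0 / (d_in + d_out))
        self.weight = Tensor(rng.uniform(-bound, bound, (d_in, d_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm1d(Module):
    """Normalizes each feature over the rows of an (n, d) matrix.

    Training with n >= 2 rows uses the batch statistics and updates the
    running estimates; inference (and the degenerate n == 1 case) uses
    the running statistics.  For healthy statistics the training batch
    should mix several groups — normalizing a single same-class group in
    isolation makes the row mean carry the class and the variance can
    collapse after attention mixing.
    """

    def __init__(self, d: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.running_mean = np.zeros(d)
        self.running_var = np.ones(d)
        self.momentum, self.eps = momentum, eps

    def buffers(self):
        yield "running_mean", self.running_mean
        yield "running_var", self.running_var

    def forward(self, x: Tensor, training: bool) -> Tensor:
        n = x.shape[0]
        if training and n >= 2:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean *= 1.0 - self.momentum
            self.running_mean += self.momentum * mu.data.ravel()
            unbiased = var.data.ravel() * n / (n - 1)
            self.running_var *= 1.0 - self.momentum
            self.running_var += self.momentum * unbiased
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x: Tensor, training: bool,
                rng: np.random.Generator | None = None) -> Tensor:
        if not training or self.rate == 0.0:
            return x
        rng = rng or np.random.default_rng()
        mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * mask


class SGD:
    """Stochastic gradient descent with momentum and decoupled-from-nothing
    classic L2 weight decay (decay added to the gradient)."""

    def __init__(self, params: list[tuple[str, Tensor]], lr: float,
                 momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = {name: np.zeros_like(p.data) for name, p in params}

    def zero_grad(self) -> None:
        for _, p in self.params:
            p.grad = None

    def step(self) -> None:
        for name, p in self.params:
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v = self.velocity[name]
            v *= self.momentum
            v += g
            p.data -= self.lr * v


def log_softmax(logits: Tensor) -> Tensor:
    """Row-wise log-softmax, max-shifted for stability."""
    shift = logits - logits.max_detached(axis=-1, keepdims=True)
    return shift - shift.exp().sum(axis=-1, keepdims=True).log()


def softmax_rows(logits: Tensor) -> Tensor:
    return log_softmax(logits).exp()
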