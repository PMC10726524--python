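"""Layers and optimizer for the autoencoder, built on :mod:`tcrvae.autodiff`.

Weight initialisation is Glorot-uniform driven by a caller-supplied
`numpy.random.Generator`, so a model is fully determined by its seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv1d


class Module:
    """Base class: tracks parameters of itself and child modules."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                out[key] = v
            elif isinstance(v, Module):
                out.update(v.named_parameters(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(prefix=f"{key}.{i}."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def glorot(rng: np.random.Generator, shape: tuple[int, ...],
           fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Module):
    """Affine map x @ W + b on the last axis."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Tensor(glorot(rng, (in_dim, out_dim), in_dim, out_dim),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.ndim == 2:
            return x @ self.weight + self.bias
        # position-wise application on (n, L, C): flatten, apply, restore
        n, L, c = x.data.shape
        out = x.reshape(n * L, c) @ self.weight + self.bias
        return out.reshape(n, L, self.weight.data.shape[1])


class Embedding(Module):
    """Trainable embedding consumed as one-hot @ table."""

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, 0.1, size=(vocab_size, dim)),
                             requires_grad=True)

    def __call__(self, onehot: Tensor) -> Tensor:
        return onehot @ self.weight


class Conv1d(Module):
    """Stride-1 same-padding convolution over (n, L, C_in) -> (n, L, C_out)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        fan_in = kernel_size * in_channels
        self.weight = Tensor(
            glorot(rng, (kernel_size, in_channels, out_channels),
                   fan_in, out_channels),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias)


class Adam:
    """Adaptive-moment optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Tensor], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
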