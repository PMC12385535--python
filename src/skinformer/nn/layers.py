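"""Minimal NumPy layer library with explicit reverse-mode gradients.

Every layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients into :class:`Parameter.grad` during
``backward``.  Gradients are checked against central finite differences in
the test suite.  All heavy math runs in float32.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

DTYPE = np.float32


class Parameter:
    """A learnable array with an accumulated gradient."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return int(self.value.size)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: tracks parameters and sub-modules by attribute name."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, attr in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(attr, Parameter):
                yield full, attr
            elif isinstance(attr, Module):
                yield from attr.named_parameters(prefix=full + ".")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.value.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=DTYPE)
            if arr.shape != p.value.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.value.shape}")
            p.value[...] = arr

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _rng_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    # Kaiming-uniform style bound, the common default for conv/linear weights.
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Linear(Module):
    """Affine map on the last axis: y = x @ W + b."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.weight = Parameter(_rng_init(rng, (in_dim, out_dim), in_dim))
        self.bias = Parameter(_rng_init(rng, (out_dim,), in_dim)) if bias else None
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.weight.value
        if self.bias is not None:
            y = y + self.bias.value
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, self.in_dim)
        dy2 = dy.reshape(-1, self.out_dim)
        self.weight.grad += x2.T @ dy2
        if self.bias is not None:
            self.bias.grad += dy2.sum(axis=0)
        return dy @ self.weight.value.T


class Conv2d(Module):
    """Valid (unpadded) strided 2-D convolution over (batch, channels, H, W)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int,
        rng: np.random.Generator,
        bias: bool = True,
    ):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        fan_in = in_channels * kernel * kernel
        self.weight = Parameter(_rng_init(rng, (out_channels, in_channels, kernel, kernel), fan_in))
        self.bias = Parameter(_rng_init(rng, (out_channels,), fan_in)) if bias else None
        self._windows: np.ndarray | None = None
        self._x_shape: tuple[int, ...] | None = None

    def output_shape(self, h: int, w: int) -> tuple[int, int]:
        k, s = self.kernel, self.stride
        if h < k or w < k:
            raise ValueError(f"input {h}x{w} smaller than kernel {k}")
        return (h - k) // s + 1, (w - k) // s + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        b, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        ho, wo = self.output_shape(h, w)
        win = np.lib.stride_tricks.sliding_window_view(x, (self.kernel, self.kernel), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride]  # (b, c, ho, wo, k, k)
        self._windows = win
        self._x_shape = x.shape
        y = np.einsum("bcxyij,ocij->boxy", win, self.weight.value, optimize=True)
        if self.bias is not None:
            y = y + self.bias.value[None, :, None, None]
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        win = self._windows
        dy = np.ascontiguousarray(dy, dtype=DTYPE)
        self.weight.grad += np.einsum("bcxyij,boxy->ocij", win, dy, optimize=True)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        b, _, ho, wo = dy.shape
        dx = np.zeros(self._x_shape, dtype=DTYPE)
        s, k = self.stride, self.kernel
        w_val = self.weight.value
        for i in range(k):
            for j in range(k):
                contrib = np.einsum("boxy,oc->bcxy", dy, w_val[:, :, i, j], optimize=True)
                dx[:, :, i : i + s * ho : s, j : j + s * wo : s] += contrib
        return dx


class LayerNorm(Module):
    """Normalization over the last axis with learnable gain/offset."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.dim = dim
        self.eps = eps
        self.gain = Parameter(np.ones(dim))
        self.offset = Parameter(np.zeros(dim))
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return xhat * self.gain.value + self.offset.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        g = self.gain.value
        flat = (-1, self.dim)
        self.gain.grad += (dy * xhat).reshape(*flat).sum(axis=0)
        self.offset.grad += dy.reshape(*flat).sum(axis=0)
        dxhat = dy * g
        n = self.dim
        # standard layer-norm backward
        dx = (dxhat - dxhat.mean(axis=-1, keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)) * inv
        return dx


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(p: np.ndarray, dp: np.ndarray, axis: int = -1) -> np.ndarray:
    """Jacobian-vector product of softmax: dz given p = softmax(z) and dL/dp."""
    return p * (dp - (dp * p).sum(axis=axis, keepdims=True))
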