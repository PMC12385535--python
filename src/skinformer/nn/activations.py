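"""Activation functions: ReLU and the learnable StarPRelu.

StarPRelu modulates a parametric ReLU by a learnable affine function of the
input magnitude::

    StarPRelu(x) = PReLU(x) * (psi * |x| + beta)
    PReLU(x)     = x            if x >= 0
                   slope * x    if x <  0

At (slope=0, psi=0, beta=1) it reduces exactly to ReLU; at (psi=0, beta=1)
it is a plain PReLU.  The learnable magnitude term keeps a nonzero gradient
for negative inputs, which counteracts the "dying ReLU" failure mode where
permanently negative pre-activations stop learning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import DTYPE, Module, Parameter


@dataclass(frozen=True)
class StarPReluParams:
    """Plain-value parameter triple for the functional form."""

    slope_alpha: float
    psi: float
    beta: float


def star_prelu(x: np.ndarray | float, params: StarPReluParams) -> np.ndarray:
    """Elementwise StarPRelu with fixed (non-learnable) parameters."""
    x = np.asarray(x, dtype=float)
    prelu = np.where(x >= 0, x, params.slope_alpha * x)
    return prelu * (params.psi * np.abs(x) + params.beta)


class StarPRelu(Module):
    """Learnable StarPRelu layer holding one scalar (slope, psi, beta) triple.

    Initialized at (0.25, 0, 1), i.e. exact PReLU behavior with the
    conventional PReLU slope, so training starts from a familiar regime.
    """

    def __init__(self, slope_alpha: float = 0.25, psi: float = 0.0, beta: float = 1.0):
        self.slope = Parameter(np.asarray(slope_alpha))
        self.psi = Parameter(np.asarray(psi))
        self.beta = Parameter(np.asarray(beta))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        a = self.slope.value
        prelu = np.where(x >= 0, x, a * x)
        return prelu * (self.psi.value * np.abs(x) + self.beta.value)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        a, psi, beta = self.slope.value, self.psi.value, self.beta.value
        neg = x < 0
        prelu = np.where(neg, a * x, x)
        mag = psi * np.abs(x) + beta
        self.slope.grad += np.asarray((dy * np.where(neg, x, 0.0) * mag).sum(), dtype=DTYPE)
        self.psi.grad += np.asarray((dy * prelu * np.abs(x)).sum(), dtype=DTYPE)
        self.beta.grad += np.asarray((dy * prelu).sum(), dtype=DTYPE)
        dprelu_dx = np.where(neg, a, 1.0)
        return dy * (dprelu_dx * mag + prelu * psi * np.sign(x))


class ReLU(Module):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(x.dtype, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(dy.dtype, copy=False)


def make_activation(name: str) -> Module:
    """Factory for the activation switch (`starprelu` / `relu`)."""
    if name == "starprelu":
        return StarPRelu()
    if name == "relu":
        return ReLU()
    raise ValueError(f"unknown activation {name!r}; expected 'starprelu' or 'relu'")
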