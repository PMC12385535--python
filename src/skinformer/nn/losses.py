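"""Enhanced Focal Loss (EFLoss) and plain cross-entropy.

For a sample with true class t, predicted class probabilities p, class
scaling factors alpha_j and hyperparameters beta > 1, 0 <= gamma < 1::

    EFLoss = beta ** sigmoid(alpha_t) * (1 - p_t) ** gamma * (-log p_t)

The reward/penalty factor beta**sigmoid(alpha_t) up-weights rare classes:
alpha_j = 1 - n_j / n_total is close to 1 for a rare class and close to 0
for a dominant one, and sigma is the logistic sigmoid (the only bounded,
increasing reading of the reward coefficient).  The (1 - p_t)**gamma term
is the usual focal down-weighting of easy examples.

With beta = 1 and gamma = 0 the loss is exactly cross-entropy; with gamma=0
alone it is cross-entropy scaled by beta**sigmoid(alpha_t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPS = 1e-12


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def class_scaling_factors(class_counts) -> np.ndarray:
    """Per-class factors alpha_j = 1 - count_j / total_count."""
    counts = np.asarray(class_counts, dtype=float)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("class_counts must be a non-empty 1-D vector")
    if (counts < 0).any():
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("at least one class must have a positive count")
    return 1.0 - counts / total


@dataclass
class EFLossConfig:
    """Hyperparameters of the Enhanced Focal Loss.

    beta: reward/penalty base, > 1 (default 3 — the training setting).
    gamma: focusing exponent in [0, 1) (default 0.3).
    class_scaling: alpha_j vector, typically from :func:`class_scaling_factors`.
    reduction: 'mean' or 'sum' over a batch.
    """

    beta: float = 3.0
    gamma: float = 0.3
    class_scaling: np.ndarray = field(default_factory=lambda: np.zeros(1))
    reduction: str = "mean"

    def __post_init__(self):
        self.class_scaling = np.asarray(self.class_scaling, dtype=float)
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")

    @property
    def class_weights(self) -> np.ndarray:
        """beta ** sigmoid(alpha_j), the per-class reward factors."""
        return self.beta ** sigmoid(self.class_scaling)


def efloss(predicted: np.ndarray, truth_class: int, config: EFLossConfig) -> float:
    """Single-sample loss for a hard label (one-hot ground truth)."""
    p = np.asarray(predicted, dtype=float)
    if not 0 <= truth_class < p.shape[-1]:
        raise ValueError(f"truth_class {truth_class} out of range for {p.shape[-1]} classes")
    pt = np.clip(p[truth_class], EPS, 1.0)
    w = config.class_weights[truth_class]
    return float(w * (1.0 - pt) ** config.gamma * (-np.log(pt)))


def efloss_batch(predicted: np.ndarray, truth, config: EFLossConfig) -> float:
    """Batch loss; `truth` is either an integer label vector or a soft-label
    matrix of per-class ground-truth probabilities (rows summing to 1)."""
    p = np.asarray(predicted, dtype=float)
    if p.ndim != 2:
        raise ValueError("predicted must be (batch, classes)")
    truth = np.asarray(truth)
    if truth.ndim == 1:
        y = np.zeros_like(p)
        if truth.shape[0] != p.shape[0]:
            raise ValueError("label count does not match batch size")
        y[np.arange(p.shape[0]), truth.astype(int)] = 1.0
    elif truth.shape == p.shape:
        y = truth.astype(float)
    else:
        raise ValueError(f"truth shape {truth.shape} incompatible with predictions {p.shape}")
    pc = np.clip(p, EPS, 1.0)
    w = config.class_weights[None, :]
    per_sample = (w * (1.0 - pc) ** config.gamma * y * (-np.log(pc))).sum(axis=1)
    return float(per_sample.mean() if config.reduction == "mean" else per_sample.sum())


def efloss_grad(predicted: np.ndarray, labels: np.ndarray, config: EFLossConfig) -> np.ndarray:
    """dLoss/dp for hard integer labels, matching :func:`efloss_batch`.

    Both (1 - p_t) and p_t are floored at EPS so the gradient stays finite
    at the boundaries of the simplex.
    """
    p = np.asarray(predicted, dtype=float)
    n, _ = p.shape
    labels = np.asarray(labels, dtype=int)
    pt = np.clip(p[np.arange(n), labels], EPS, 1.0 - EPS)
    q = 1.0 - pt
    w = config.class_weights[labels]
    g = config.gamma
    dpt = w * (g * q ** (g - 1.0) * np.log(pt) - q ** g / pt) if g > 0 else -w / pt
    grad = np.zeros_like(p)
    grad[np.arange(n), labels] = dpt
    if config.reduction == "mean":
        grad /= n
    return grad


def cross_entropy_batch(predicted: np.ndarray, labels: np.ndarray, reduction: str = "mean") -> float:
    """Plain multiclass cross-entropy on probabilities (hard labels)."""
    p = np.asarray(predicted, dtype=float)
    n = p.shape[0]
    pt = np.clip(p[np.arange(n), np.asarray(labels, dtype=int)], EPS, 1.0)
    per_sample = -np.log(pt)
    return float(per_sample.mean() if reduction == "mean" else per_sample.sum())


def make_loss(name: str, class_counts, beta: float = 3.0, gamma: float = 0.3) -> EFLossConfig:
    """Loss switch: 'efloss' uses the class-frequency factors, 'ce' is plain
    cross-entropy expressed as the (beta=1, gamma=0, alpha=0) special case."""
    counts = np.asarray(class_counts, dtype=float)
    if name == "efloss":
        return EFLossConfig(beta=beta, gamma=gamma, class_scaling=class_scaling_factors(counts))
    if name == "ce":
        return EFLossConfig(beta=1.0, gamma=0.0, class_scaling=np.zeros(counts.shape[0]))
    raise ValueError(f"unknown loss {name!r}; expected 'efloss' or 'ce'")
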