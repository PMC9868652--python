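"""Minimal neural-network primitives used by the structured models.

The networks here are small enough (a few hundred scalar embeddings) that
a hand-vectorized numpy implementation with explicit backpropagation is
both fast and exactly auditable — in particular the group-structure
masking is applied to weights *and* gradients, so cross-group gradients
are identically zero rather than merely small.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "log_softmax", "nll_loss"]


def log_softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise log-softmax, numerically stable."""
    z = logits - logits.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def nll_loss(logp: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log-likelihood of integer labels under row log-probs."""
    return float(-logp[np.arange(len(y)), y].mean())


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
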