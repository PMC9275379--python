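"""Shared optimizer, activations and loss for the numpy networks."""
from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_softmax_ce(
    logits: np.ndarray, y: np.ndarray, sample_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-weighted cross-entropy; returns (loss, dlogits).

    Per-sample losses are weighted and averaged by the total weight, so
    reweighting the classes rescales their error costs without changing
    the overall loss scale.
    """
    n = logits.shape[0]
    p = softmax(logits)
    w = np.asarray(sample_weights, dtype=float)
    total = w.sum()
    loss = float(-(w * np.log(np.clip(p[np.arange(n), y], 1e-12, None))).sum() / total)
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / total)[:, None]
    return loss, dlogits


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def glorot_init(rng: np.random.Generator, shape: tuple[int, ...],
                fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimizer over a name->array parameter dict (in-place updates)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for name, g in grads.items():
            if name not in self._m:
                self._m[name] = np.zeros_like(g)
                self._v[name] = np.zeros_like(g)
            m = self._m[name]
            v = self._v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
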