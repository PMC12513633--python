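"""Minimal dense neural networks with explicit reverse-mode gradients.

The drift and diffusion fields of the reconstructed SDE, the recurrent
baselines, and the noise-intensity regressor are all small multilayer
perceptrons.  Because the training loss is backpropagated through an
Euler--Maruyama unroll (a bespoke computation graph), the networks expose
an explicit ``forward`` that returns a cache and a ``backward`` that
consumes an upstream gradient and returns both the input gradient and the
parameter gradients.  Everything is plain numpy.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["MLP", "Adam", "global_norm_clip"]


class MLP:
    """Fully connected network with tanh hidden activations and linear output.

    Parameters
    ----------
    sizes:
        Layer widths, input first, output last, e.g. ``(4, 48, 48, 2)``.
    rng:
        numpy Generator used for initialization.
    out_scale:
        Multiplier on the output layer's initial weights.  Values < 1 start
        the network near the zero function, which keeps the initial SDE
        simulation tame.
    """

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator,
                 out_scale: float = 1.0) -> None:
        self.sizes = tuple(int(s) for s in sizes)
        if len(self.sizes) < 2:
            raise ValueError("need at least input and output layer")
        self.weights: List[np.ndarray] = []
        self.biases: List[np.ndarray] = []
        for i, (fan_in, fan_out) in enumerate(zip(self.sizes[:-1], self.sizes[1:])):
            scale = np.sqrt(1.0 / fan_in)
            if i == len(self.sizes) - 2:
                scale *= out_scale
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    # -- parameter flattening (used by the optimizer) ---------------------
    @property
    def params(self) -> List[np.ndarray]:
        return self.weights + self.biases

    def zero_grads(self) -> List[np.ndarray]:
        return [np.zeros_like(p) for p in self.params]

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray) -> Tuple[np.ndarray, list]:
        """Return (output, cache); ``x`` has shape (n, sizes[0])."""
        h = np.asarray(x, dtype=float)
        cache = [h]
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < n_layers - 1:
                h = np.tanh(h)
            cache.append(h)
        return h, cache

    def value(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, cache: list, upstream: np.ndarray,
                 grads: List[np.ndarray]) -> np.ndarray:
        """Accumulate parameter gradients into ``grads``; return d(loss)/d(input).

        ``grads`` must have the layout of :meth:`zero_grads` (weights then
        biases) and is accumulated in place so one backward pass per
        integration step can share a single gradient buffer.
        """
        n_layers = len(self.weights)
        delta = np.asarray(upstream, dtype=float)
        for i in range(n_layers - 1, -1, -1):
            if i < n_layers - 1:
                # cache[i + 1] stores the post-tanh activation
                delta = delta * (1.0 - cache[i + 1] ** 2)
            grads[i] += cache[i].T @ delta
            grads[n_layers + i] += delta.sum(axis=0)
            delta = delta @ self.weights[i].T
        return delta


class Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    def __init__(self, params: List[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0) -> None:
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                p -= self.lr * self.weight_decay * p


def global_norm_clip(grads: List[np.ndarray], max_norm: float) -> float:
    """Scale ``grads`` in place so their joint l2 norm is at most ``max_norm``."""
    total = float(np.sqrt(sum(float(np.sum(g * g)) for g in grads)))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale
    return total
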