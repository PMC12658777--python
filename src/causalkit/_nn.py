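"""Minimal feedforward-network primitives with manual backprop.

Compact numpy building blocks — dense layers with ReLU, inverted dropout,
and an Adam optimizer — shared by the DAG-constrained structure learner and
the causal-effect variational autoencoder.  Sized for desk-scale problems
(n up to a few thousand, a few dozen features); everything is seeded.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "MLP"]


class Adam:
    """Adam over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params, lr=1e-2, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class MLP:
    """Fully connected ReLU network with a linear head and optional dropout.

    ``forward`` caches activations for ``backward``, which returns the
    gradient w.r.t. the input and fills ``self.grads`` (aligned with
    ``self.params``).  Dropout uses inverted scaling and is active whenever
    a mask-generating rng is passed, which is how Monte-Carlo dropout at
    inference is realized.
    """

    def __init__(self, sizes, rng, dropout_rate=0.0):
        self.W, self.b = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.W.append(rng.standard_normal((fan_in, fan_out)) * scale)
            self.b.append(np.zeros(fan_out))
        self.dropout_rate = dropout_rate
        self._cache = None

    @property
    def params(self):
        return [*self.W, *self.b]

    def forward(self, X, dropout_rng=None):
        h = X
        hs, masks = [X], []
        L = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < L - 1:
                h = np.maximum(h, 0.0)
                if self.dropout_rate > 0 and dropout_rng is not None:
                    keep = 1.0 - self.dropout_rate
                    mask = (dropout_rng.random(h.shape) < keep) / keep
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            hs.append(h)
        self._cache = (hs, masks)
        return h

    def backward(self, dout):
        hs, masks = self._cache
        L = len(self.W)
        dW = [None] * L
        db = [None] * L
        d = dout
        for i in reversed(range(L)):
            h_in = hs[i]
            dW[i] = h_in.T @ d
            db[i] = d.sum(axis=0)
            d = d @ self.W[i].T
            if i > 0:
                if masks[i - 1] is not None:
                    d = d * masks[i - 1]
                d = d * (hs[i] > 0)
        self.grads = [*dW, *db]
        return d
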