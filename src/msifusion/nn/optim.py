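"""Adam optimizer and the cross-entropy training loss."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Adam:
    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cross_entropy(logits, labels):
    """Mean negative log-likelihood of integer ``labels`` under softmax logits."""
    labels = np.asarray(labels)
    n, k = logits.shape
    onehot = np.zeros((n, k), dtype=logits.data.dtype)
    onehot[np.arange(n), labels] = 1.0
    logp = ad.log_softmax(logits, axis=1)
    return -ad.reduce_mean(ad.reduce_sum(logp * Tensor(onehot), axis=1))
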