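"""AdamW with optional cosine learning-rate decay."""

from __future__ import annotations

import math

import numpy as np


__all__ = ["AdamW", "cosine_lr"]


class AdamW:
    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.wd * p.data)


def cosine_lr(base_lr: float, step: int, total_steps: int,
              min_frac: float = 0.05, warmup_frac: float = 0.05) -> float:
    """Linear warmup to base_lr, then cosine decay to min_frac*base_lr.

    Warmup stabilizes the attention blocks early in training, which
    otherwise converge erratically from a cold start."""
    if total_steps <= 1:
        return base_lr
    warmup_steps = max(int(warmup_frac * total_steps), 1)
    if warmup_frac > 0 and step < warmup_steps:
        return base_lr * (step + 1) / warmup_steps
    frac = min((step - warmup_steps) / max(total_steps - warmup_steps - 1, 1),
               1.0)
    return base_lr * (min_frac + (1.0 - min_frac)
                      * 0.5 * (1.0 + math.cos(math.pi * frac)))
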