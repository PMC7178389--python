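"""Optimizers (AdamW, AdaMax) and the one-cycle learning-rate schedule.

Optimizers operate on parameter groups so that fine-tuning can assign
discriminative (per-layer-group) learning rates: each group carries an
``lr_scale`` multiplying the schedule's current base rate.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor


class _AdamBase:
    def __init__(self, param_groups, lr, betas=(0.9, 0.99), eps=1e-8, weight_decay=0.0):
        # param_groups: list of dicts {"params": [...], "lr_scale": float}
        if param_groups and isinstance(param_groups[0], Tensor):
            param_groups = [{"params": list(param_groups), "lr_scale": 1.0}]
        self.param_groups = param_groups
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def zero_grad(self):
        for g in self.param_groups:
            for p in g["params"]:
                p.zero_grad()

    def _moments(self, p: Tensor):
        st = self._state.get(id(p))
        if st is None:
            st = (np.zeros_like(p.data), np.zeros_like(p.data))
            self._state[id(p)] = st
        return st


class AdamW(_AdamBase):
    """Adam with decoupled weight decay."""

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for group in self.param_groups:
            lr = self.lr * group.get("lr_scale", 1.0)
            for p in group["params"]:
                if not p.requires_grad or p.grad is None:
                    continue
                m, v = self._moments(p)
                m *= b1
                m += (1 - b1) * p.grad
                v *= b2
                v += (1 - b2) * p.grad**2
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps)
                                + self.weight_decay * p.data)


class AdaMax(_AdamBase):
    """Adam variant based on the infinity norm."""

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for group in self.param_groups:
            lr = self.lr * group.get("lr_scale", 1.0)
            for p in group["params"]:
                if not p.requires_grad or p.grad is None:
                    continue
                m, u = self._moments(p)
                m *= b1
                m += (1 - b1) * p.grad
                np.maximum(b2 * u, np.abs(p.grad), out=u)
                p.data -= lr / (1 - b1**self.t) * m / (u + self.eps)


def one_cycle_schedule(n_steps: int, max_lr: float, pct_start: float = 0.3,
                       div_start: float = 25.0, div_final: float = 1e4):
    """Cosine-annealed one-cycle learning-rate trace.

    The rate rises from ``max_lr/div_start`` to ``max_lr`` over the first
    ``pct_start`` of steps, then falls to ``max_lr/div_final``; rise and fall
    are half-cosines.  Returns an array of length ``n_steps``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    up = max(1, int(round(n_steps * pct_start)))
    down = max(1, n_steps - up)
    lrs = np.empty(n_steps)
    lo0, lo1 = max_lr / div_start, max_lr / div_final
    for i in range(up):
        t = i / max(1, up - 1)  # peak is attained at the end of the rise
        lrs[i] = lo0 + (max_lr - lo0) * (1 - math.cos(math.pi * t)) / 2
    for i in range(n_steps - up):
        t = (i + 1) / down
        lrs[up + i] = max_lr + (lo1 - max_lr) * (1 - math.cos(math.pi * t)) / 2
    return lrs
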