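"""Optimisers."""

from __future__ import annotations

import numpy as np

from .modules import Parameter

__all__ = ["SGD"]


class SGD:
    """SGD with classical momentum and decoupled-style weight decay.

    Matches the common detector training recipe: velocity
    ``v <- mu * v + grad + wd * w`` and ``w <- w - lr * v``.  BatchNorm
    parameters and biases are conventionally excluded from weight decay by
    passing them in a second parameter group with ``weight_decay=0``.
    """

    def __init__(self, param_groups, lr: float = 0.01, momentum: float = 0.937,
                 weight_decay: float = 0.0):
        if param_groups and isinstance(param_groups[0], Parameter):
            param_groups = [{"params": list(param_groups)}]
        self.groups = []
        for group in param_groups:
            g = {"lr": lr, "momentum": momentum, "weight_decay": weight_decay}
            g.update(group)
            g["params"] = list(g["params"])
            self.groups.append(g)
        self._velocity: dict[int, np.ndarray] = {}
        self.lr = lr

    def set_lr(self, lr: float) -> None:
        self.lr = lr
        for g in self.groups:
            g["lr"] = lr

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self) -> None:
        for g in self.groups:
            lr, mu, wd = g["lr"], g["momentum"], g["weight_decay"]
            for p in g["params"]:
                if p.grad is None:
                    continue
                grad = p.grad.astype(np.float32, copy=False)
                if wd:
                    grad = grad + wd * p.data
                v = self._velocity.get(id(p))
                if v is None:
                    v = np.zeros_like(p.data)
                    self._velocity[id(p)] = v
                v *= mu
                v += grad
                p.data = p.data - lr * v
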