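"""First-order optimizers: Adam, RMSprop and Adadelta."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class Optimizer:
    def __init__(self, params: list[Tensor]):
        self.params = list(params)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        raise NotImplementedError


class Adam(Optimizer):
    def __init__(self, params, lr=0.00033, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, params, lr=0.001, rho=0.9, eps=1e-7):
        super().__init__(params)
        self.lr, self.rho, self.eps = lr, rho, eps
        self.sq = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, s in zip(self.params, self.sq):
            if p.grad is None:
                continue
            g = p.grad
            s *= self.rho
            s += (1 - self.rho) * g * g
            p.data -= self.lr * g / (np.sqrt(s) + self.eps)


class Adadelta(Optimizer):
    def __init__(self, params, lr=1.0, rho=0.95, eps=1e-7):
        super().__init__(params)
        self.lr, self.rho, self.eps = lr, rho, eps
        self.sq = [np.zeros_like(p.data) for p in self.params]
        self.dx = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, s, d in zip(self.params, self.sq, self.dx):
            if p.grad is None:
                continue
            g = p.grad
            s *= self.rho
            s += (1 - self.rho) * g * g
            update = np.sqrt(d + self.eps) / np.sqrt(s + self.eps) * g
            d *= self.rho
            d += (1 - self.rho) * update * update
            p.data -= self.lr * update


_OPTIMIZERS = {"adam": Adam, "rmsprop": RMSprop, "adadelta": Adadelta}


def make_optimizer(name: str, params, lr: float) -> Optimizer:
    try:
        cls = _OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}") from None
    return cls(params, lr=lr)
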