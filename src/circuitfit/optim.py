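"""Adam and RMSProp updates operating in place on parameter tensors."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Adam", "RMSProp", "make_optimizer"]


class _Optimizer:
    def __init__(self, params, lr):
        self.params = list(params)
        self.lr = float(lr)

    def step(self, grads):
        raise NotImplementedError


class Adam(_Optimizer):
    """Adam with the (beta1=0.5, beta2=0.9) profile used for GAN training."""

    def __init__(self, params, lr, beta1=0.5, beta2=0.9, eps=1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.data if isinstance(g, Tensor) else np.asarray(g)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSProp(_Optimizer):
    def __init__(self, params, lr, rho=0.9, eps=1e-6):
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self.sq = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads):
        for p, g, s in zip(self.params, grads, self.sq):
            g = g.data if isinstance(g, Tensor) else np.asarray(g)
            s *= self.rho
            s += (1 - self.rho) * g * g
            p.data -= self.lr * g / (np.sqrt(s) + self.eps)


def make_optimizer(name, params, lr):
    name = name.lower()
    if name == "adam":
        return Adam(params, lr)
    if name == "rmsprop":
        return RMSProp(params, lr)
    raise ValueError(f"unknown optimizer {name!r}")
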