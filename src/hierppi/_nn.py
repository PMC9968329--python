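"""Layers and optimizer built on the autodiff core: Linear, BatchNorm, Adam."""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear:
    """Affine map y = x W + b."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.W = Tensor(glorot_uniform(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros((1, d_out)), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class BatchNorm1d:
    """Feature-wise batch normalization over rows (nodes of a graph).

    Training mode normalizes with batch statistics and updates exponential
    running averages; eval mode uses the running statistics, which makes the
    layer a fixed per-row affine map (required for block-diagonal batching to
    match the per-graph loop bit for bit).
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, dim)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, dim)), requires_grad=True)
        self.running_mean = np.zeros((1, dim))
        self.running_var = np.ones((1, dim))
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            n = x.shape[0]
            unbiased = var.data * (n / max(n - 1, 1))
            self.running_var = (1 - m) * self.running_var + m * unbiased
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            xhat = (x - Tensor(self.running_mean)) * Tensor(
                (self.running_var + self.eps) ** -0.5
            )
        return self.gamma * xhat + self.beta

    def apply_multi(self, xs):
        """Normalize a list of row-blocks with *joint* statistics.

        Equivalent to concatenating the blocks, applying the layer, and
        splitting back — but without materializing the concatenation, which
        keeps the backward pass allocation-light for many small blocks.
        """
        if not self.training:
            return [self(x) for x in xs]
        n_total = sum(x.shape[0] for x in xs)
        total = xs[0].sum(axis=0, keepdims=True)
        for x in xs[1:]:
            total = total + x.sum(axis=0, keepdims=True)
        mu = total * (1.0 / n_total)
        sq = ((xs[0] - mu) ** 2.0).sum(axis=0, keepdims=True)
        for x in xs[1:]:
            sq = sq + ((x - mu) ** 2.0).sum(axis=0, keepdims=True)
        var = sq * (1.0 / n_total)
        m = self.momentum
        self.running_mean = (1 - m) * self.running_mean + m * mu.data
        unbiased = var.data * (n_total / max(n_total - 1, 1))
        self.running_var = (1 - m) * self.running_var + m * unbiased
        scale = (var + self.eps) ** -0.5
        return [self.gamma * ((x - mu) * scale) + self.beta for x in xs]

    def parameters(self):
        return [self.gamma, self.beta]

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def load_state(self, state):
        self.running_mean = np.asarray(state["running_mean"], dtype=np.float64)
        self.running_var = np.asarray(state["running_var"], dtype=np.float64)


class Adam:
    """Adam optimizer (bias-corrected first/second moments)."""

    def __init__(self, params, lr: float = 0.001, beta1: float = 0.99,
                 beta2: float = 0.99, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def set_training(modules, flag: bool):
    for mod in modules:
        if isinstance(mod, BatchNorm1d):
            mod.training = flag
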