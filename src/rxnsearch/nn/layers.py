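"""Parameterized layers built on the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Linear:
    """Affine map y = x W + b (bias optional; Glorot-uniform init)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    def parameters(self) -> list[Tensor]:
        return [self.W] if self.b is None else [self.W, self.b]

    def state(self) -> dict[str, np.ndarray]:
        d = {"W": self.W.data}
        if self.b is not None:
            d["b"] = self.b.data
        return d

    def load_state(self, d: dict[str, np.ndarray]) -> None:
        self.W.data = np.asarray(d["W"], dtype=np.float64)
        if self.b is not None:
            self.b.data = np.asarray(d["b"], dtype=np.float64)


class BatchNorm:
    """1-D batch normalization over rows with running statistics.

    In training mode batch statistics are used and running stats updated;
    in eval mode the frozen running statistics are applied (a per-feature
    affine map, so outputs for one row do not depend on the rest of the
    batch).
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training and x.shape[0] > 1:
            mu = x.mean(axis=0)
            xc = x - mu
            var = (xc * xc).mean(axis=0)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data
            )
            n = x.shape[0]
            unbiased = var.data * n / max(n - 1, 1)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * unbiased
            )
            inv = (var + self.eps) ** -0.5
            return xc * inv * self.gamma + self.beta
        xc = x - Tensor(self.running_mean)
        inv = Tensor(1.0 / np.sqrt(self.running_var + self.eps))
        return xc * inv * self.gamma + self.beta

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def state(self) -> dict[str, np.ndarray]:
        return {
            "gamma": self.gamma.data,
            "beta": self.beta.data,
            "running_mean": self.running_mean,
            "running_var": self.running_var,
        }

    def load_state(self, d: dict[str, np.ndarray]) -> None:
        self.gamma.data = np.asarray(d["gamma"], dtype=np.float64)
        self.beta.data = np.asarray(d["beta"], dtype=np.float64)
        self.running_mean = np.asarray(d["running_mean"], dtype=np.float64)
        self.running_var = np.asarray(d["running_var"], dtype=np.float64)
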