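"""Dense layers, multilayer perceptrons and the Adam optimizer.

Everything here is built on :mod:`jointomics.autodiff`.  Layers hold their
weights as :class:`~jointomics.autodiff.Tensor` leaves; ``forward`` builds a
graph when called with Tensors (or with ``numpy=False``) and runs as plain
numpy when called with ``numpy=True`` (used for deterministic, sampling-free
evaluation such as imputation).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

_ACTIVATIONS = {
    "relu": ad.relu,
    "tanh": ad.tanh,
    "sigmoid": ad.sigmoid,
    "softplus": ad.softplus,
}


class Dense:
    """Affine layer ``x @ W + b`` with Glorot-uniform initialization."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(d_in, d_out)))
        self.b = Tensor(np.zeros(d_out))

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x, *, numpy: bool = False):
        if numpy:
            return ad.value_of(x) @ self.W.value + self.b.value
        return ad.matmul(x, self.W) + self.b


class BatchNorm:
    """1-D batch normalization with running statistics for evaluation."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim))
        self.beta = Tensor(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, *, train: bool, numpy: bool = False):
        if train:
            mu = ad.mean_(x, axis=0, keepdims=True)
            centered = x - mu
            var = ad.mean_(centered ** 2, axis=0, keepdims=True)
            xhat = centered / ad.sqrt(var + self.eps)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * ad.value_of(mu).ravel()
            self.running_var = m * self.running_var + (1 - m) * ad.value_of(var).ravel()
        else:
            xv = ad.value_of(x) if numpy else x
            xhat = (xv - self.running_mean) / np.sqrt(self.running_var + self.eps)
        if numpy:
            return ad.value_of(xhat) * self.gamma.value + self.beta.value
        return xhat * self.gamma + self.beta


class MLP:
    """Feed-forward network: hidden layers with activation/dropout/batchnorm,
    then a linear output layer of width ``d_out``."""

    def __init__(
        self,
        d_in: int,
        hidden: list[int],
        d_out: int,
        rng: np.random.Generator,
        activation: str = "relu",
        dropout: float = 0.0,
        batch_norm: bool = False,
    ):
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.dropout = float(dropout)
        self.layers: list[Dense] = []
        self.norms: list[BatchNorm | None] = []
        prev = d_in
        for h in hidden:
            self.layers.append(Dense(prev, h, rng))
            self.norms.append(BatchNorm(h) if batch_norm else None)
            prev = h
        self.out = Dense(prev, d_out, rng)

    def parameters(self):
        params = []
        for layer, norm in zip(self.layers, self.norms):
            params.extend(layer.parameters())
            if norm is not None:
                params.extend(norm.parameters())
        params.extend(self.out.parameters())
        return params

    def forward(self, x, *, train: bool = False, rng: np.random.Generator | None = None,
                numpy: bool = False):
        act = _ACTIVATIONS[self.activation]
        h = x
        for layer, norm in zip(self.layers, self.norms):
            h = layer.forward(h, numpy=numpy)
            if norm is not None:
                h = norm.forward(h, train=train, numpy=numpy)
            h = act(h)
            if train and self.dropout > 0.0:
                if rng is None:
                    raise ValueError("dropout during training requires an rng")
                keep = (rng.random(ad.value_of(h).shape) >= self.dropout).astype(float)
                h = h * (keep / (1.0 - self.dropout))
        return self.out.forward(h, numpy=numpy)

    # -- checkpointing -------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        arrs = [p.value for p in self.parameters()]
        for norm in self.norms:
            if norm is not None:
                arrs.extend([norm.running_mean, norm.running_var])
        return arrs

    def load_state_arrays(self, arrs: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, a in zip(params, arrs[: len(params)]):
            p.value = np.asarray(a, dtype=np.float64)
        rest = arrs[len(params):]
        i = 0
        for norm in self.norms:
            if norm is not None:
                norm.running_mean = np.asarray(rest[i])
                norm.running_var = np.asarray(rest[i + 1])
                i += 2


class Adam:
    """Adam with the standard bias correction (Kingma & Ba defaults)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)
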