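"""Minimal fully-connected network with analytic derivatives.

A small numpy MLP used as the noise-prediction head of a learned score model.
Derivatives are computed analytically in both directions:

* reverse mode (backprop) for parameter gradients during training;
* forward mode (Jacobian-vector products) for exact spatial derivatives of
  the output with respect to the input, which the likelihood integrands need
  for the score divergence.

Activations are ``tanh`` — smooth, so the score field is twice
differentiable and its divergence is well defined everywhere.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GaussianFourierFeatures", "MLP", "Adam"]


class GaussianFourierFeatures:
    """Random Fourier embedding of the scalar diffusion time.

    ``embed(t) = [sin(2 pi f_k t), cos(2 pi f_k t)]`` with frozen frequencies
    ``f_k ~ N(0, scale^2)``.  Gives the network a smooth, high-resolution view
    of t, which spans four orders of magnitude in noise level.
    """

    def __init__(self, dim: int, scale: float, rng: np.random.Generator):
        if dim % 2 != 0:
            raise ValueError("embedding dim must be even")
        self.freqs = rng.normal(0.0, scale, size=dim // 2)

    @property
    def dim(self) -> int:
        return 2 * len(self.freqs)

    def embed(self, t: np.ndarray) -> np.ndarray:
        # t: (m,) -> (m, dim)
        arg = 2.0 * np.pi * np.outer(t, self.freqs)
        return np.concatenate([np.sin(arg), np.cos(arg)], axis=1)


class MLP:
    """Plain tanh MLP with manual reverse- and forward-mode differentiation."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        if len(sizes) < 2:
            raise ValueError("need at least input and output sizes")
        self.sizes = list(sizes)
        self.Ws, self.bs = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.Ws.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.bs.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.Ws)

    def forward(self, a: np.ndarray, want_cache: bool = False):
        """Forward pass; ``a`` has shape (m, sizes[0]).

        With ``want_cache`` returns (output, cache) where cache holds the
        post-activation of every layer for subsequent backprop / JVPs.
        """
        cache = [a] if want_cache else None
        for i, (W, b) in enumerate(zip(self.Ws, self.bs)):
            a = a @ W + b
            if i < self.n_layers - 1:
                a = np.tanh(a)
            if want_cache:
                cache.append(a)
        return (a, cache) if want_cache else a

    def backward(self, cache, dout: np.ndarray):
        """Reverse-mode pass: gradients of sum(dout * output) w.r.t. params.

        Returns (dWs, dbs) matching the shapes of Ws and bs.
        """
        dWs = [None] * self.n_layers
        dbs = [None] * self.n_layers
        grad = dout
        for i in range(self.n_layers - 1, -1, -1):
            if i < self.n_layers - 1:
                grad = grad * (1.0 - cache[i + 1] ** 2)  # through tanh
            dWs[i] = cache[i].T @ grad
            dbs[i] = grad.sum(axis=0)
            if i > 0:
                grad = grad @ self.Ws[i].T
        return dWs, dbs

    def input_jvp(self, cache, da: np.ndarray) -> np.ndarray:
        """Forward-mode pass: d(output) for an input perturbation ``da``.

        Exact directional derivative of the network output along ``da``,
        reusing the cached activations; shape (m, sizes[-1]).
        """
        for i, W in enumerate(self.Ws):
            da = da @ W
            if i < self.n_layers - 1:
                da = da * (1.0 - cache[i + 1] ** 2)
        return da

    # -- flat parameter access for checkpointing ------------------------
    def get_params(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (W, b) in enumerate(zip(self.Ws, self.bs)):
            out[f"W{i}"] = W
            out[f"b{i}"] = b
        return out

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for i in range(self.n_layers):
            self.Ws[i] = np.asarray(params[f"W{i}"], dtype=float)
            self.bs[i] = np.asarray(params[f"b{i}"], dtype=float)


class Adam:
    """Adam optimizer over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
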