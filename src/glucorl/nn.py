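"""Minimal fully-connected neural-network layers with manual backprop.

Only what the Q-networks need: plain linear layers, factorized-Gaussian
noisy linear layers, ReLU, and the Adam optimizer. Weight initialization
follows the familiar fan-in uniform scheme U(-1/sqrt(fan_in), 1/sqrt(fan_in))
for means and biases; noisy layers start their noise scales at
sigma0 / sqrt(fan_in) with sigma0 = 0.5.

All arrays are float64 and every source of randomness is an explicit
``numpy.random.Generator``, so training runs are reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Linear", "NoisyLinear", "ReLU", "MLP", "Adam", "noisy_linear_forward"]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=float)
        self.grad = np.zeros_like(self.data)


class Linear:
    """Affine layer y = x W + b for batched row-vector inputs."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)
        self.w = Param(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.b = Param(rng.uniform(-bound, bound, size=n_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.data + self.b.data

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ grad_out
        self.b.grad += grad_out.sum(axis=0)
        return grad_out @ self.w.data.T

    def parameters(self) -> list[Param]:
        return [self.w, self.b]


def _signed_sqrt(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.sqrt(np.abs(x))


class NoisyLinear:
    """Linear layer with learned factorized Gaussian parameter noise.

    Effective weights are ``w_mu + w_sigma * (f(eps_in) x f(eps_out))`` with
    ``f(z) = sign(z) sqrt(|z|)``; biases analogously with ``f(eps_out)``.
    The noise sample is held fixed until :meth:`resample_noise` is called
    (one sample per training batch), and :meth:`zero_noise` switches the
    layer to its deterministic mean behaviour for greedy evaluation.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 sigma0: float = 0.5):
        bound = 1.0 / np.sqrt(n_in)
        self.w_mu = Param(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.b_mu = Param(rng.uniform(-bound, bound, size=n_out))
        self.w_sigma = Param(np.full((n_in, n_out), sigma0 / np.sqrt(n_in)))
        self.b_sigma = Param(np.full(n_out, sigma0 / np.sqrt(n_in)))
        self._eps_w = np.zeros((n_in, n_out))
        self._eps_b = np.zeros(n_out)
        self._x: np.ndarray | None = None

    def resample_noise(self, rng: np.random.Generator) -> None:
        f_in = _signed_sqrt(rng.standard_normal(self.w_mu.data.shape[0]))
        f_out = _signed_sqrt(rng.standard_normal(self.w_mu.data.shape[1]))
        self._eps_w = np.outer(f_in, f_out)
        self._eps_b = f_out

    def zero_noise(self) -> None:
        self._eps_w = np.zeros_like(self._eps_w)
        self._eps_b = np.zeros_like(self._eps_b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        w = self.w_mu.data + self.w_sigma.data * self._eps_w
        b = self.b_mu.data + self.b_sigma.data * self._eps_b
        return x @ w + b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        dw = self._x.T @ grad_out
        db = grad_out.sum(axis=0)
        self.w_mu.grad += dw
        self.w_sigma.grad += dw * self._eps_w
        self.b_mu.grad += db
        self.b_sigma.grad += db * self._eps_b
        w = self.w_mu.data + self.w_sigma.data * self._eps_w
        return grad_out @ w.T

    def parameters(self) -> list[Param]:
        return [self.w_mu, self.b_mu, self.w_sigma, self.b_sigma]


def noisy_linear_forward(
    inputs: np.ndarray,
    mean_weights: np.ndarray,
    mean_bias: np.ndarray,
    weight_scales: np.ndarray,
    bias_scales: np.ndarray,
    noise_in: np.ndarray,
    noise_out: np.ndarray,
) -> np.ndarray:
    """Functional form of the noisy affine map (factorized noise).

    With zero noise samples this reduces exactly to the deterministic mean
    layer ``inputs @ mean_weights + mean_bias``.
    """
    eps_w = np.outer(_signed_sqrt(noise_in), _signed_sqrt(noise_out))
    eps_b = _signed_sqrt(noise_out)
    w = mean_weights + weight_scales * eps_w
    b = mean_bias + bias_scales * eps_b
    return np.asarray(inputs) @ w + b


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask

    def parameters(self) -> list[Param]:
        return []


class MLP:
    """A stack of layers with ReLU between every pair of linear layers.

    ``noisy_from`` marks the index (into the linear layers) from which
    layers are noisy; ``None`` means all-plain, ``0`` all-noisy.
    """

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 noisy_from: int | None = None):
        self.layers: list = []
        n_linear = len(dims) - 1
        for i in range(n_linear):
            noisy = noisy_from is not None and i >= noisy_from
            cls = NoisyLinear if noisy else Linear
            self.layers.append(cls(dims[i], dims[i + 1], rng))
            if i < n_linear - 1:
                self.layers.append(ReLU())

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def parameters(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.parameters()]

    def noisy_layers(self) -> list[NoisyLinear]:
        return [l for l in self.layers if isinstance(l, NoisyLinear)]


class Adam:
    """Adam optimizer over a fixed list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self._t += 1
        b1t = 1.0 - self.beta1 ** self._t
        b2t = 1.0 - self.beta2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m[...] = self.beta1 * m + (1.0 - self.beta1) * p.grad
            v[...] = self.beta2 * v + (1.0 - self.beta2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
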