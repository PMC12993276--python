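"""Feed-forward building blocks and the Adam optimizer.

Layers hold their parameters as :class:`~scdmac.autograd.Tensor` leaves with
``requires_grad=True``; a forward pass builds the tape, ``loss.backward()``
fills ``.grad``, and :class:`Adam` consumes and clears them.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .autograd import Tensor

Activation = Callable[[Tensor], Tensor]


def elu(x: Tensor) -> Tensor:
    return x.elu()


def relu(x: Tensor) -> Tensor:
    return x.relu()


def identity(x: Tensor) -> Tensor:
    return x


class Dense:
    """Fully connected layer with Glorot-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.b]


class MLP:
    """Stack of Dense layers with a shared hidden activation.

    The output layer uses `out_activation` (identity by default, matching a
    final linear transformation).
    """

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator,
                 hidden_activation: Activation = elu,
                 out_activation: Activation = identity):
        if len(sizes) < 2:
            raise ValueError("MLP needs at least input and output sizes")
        self.layers = [Dense(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self.hidden_activation = hidden_activation
        self.out_activation = out_activation

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = self.hidden_activation(layer(x))
        return self.out_activation(self.layers[-1](x))

    @property
    def params(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.params]


class Adam:
    """Adam with bias correction; grads are zeroed after each step."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
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
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
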