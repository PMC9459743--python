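"""Minimal NumPy neural-network kernels for the dilated TCN.

No deep-learning framework is available in the target environment, and the
network is small (tens of thousands of parameters, 8-frame windows), so the
forward/backward passes are written directly against BLAS-backed matmuls.
All tensors are float32; time-major layout is ``(batch, time, channels)``.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """A differentiable layer with explicit parameter storage."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params)


def _he_init(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class DilatedConv1d(Layer):
    """1-D convolution over time with dilation and zero same-padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k, self.d = c_in, c_out, kernel, dilation
        self.W = _he_init(rng, c_in * kernel, (c_in * kernel, c_out))
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        span = self.d * (self.k - 1)
        left = span // 2
        right = span - left
        xp = np.zeros((B, T + span, C), dtype=np.float32)
        xp[:, left : left + T] = x
        # patch t gathers frames t + j*d of the padded series, j = 0..k-1
        cols = np.empty((B, T, self.k, C), dtype=np.float32)
        for j in range(self.k):
            cols[:, :, j, :] = xp[:, j * self.d : j * self.d + T, :]
        return cols.reshape(B, T, self.k * C)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols = self._im2col(x)
        if train:
            self._cols = cols
            self._in_shape = x.shape
        return cols @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, T, _ = g.shape
        cols2d = self._cols.reshape(B * T, self.k * self.c_in)
        g2d = g.reshape(B * T, self.c_out)
        self.grads[0] += cols2d.T @ g2d
        self.grads[1] += g2d.sum(axis=0)
        gcols = (g2d @ self.W.T).reshape(B, T, self.k, self.c_in)
        span = self.d * (self.k - 1)
        left = span // 2
        gxp = np.zeros((B, T + span, self.c_in), dtype=np.float32)
        for j in range(self.k):
            gxp[:, j * self.d : j * self.d + T, :] += gcols[:, :, j, :]
        return gxp[:, left : left + T, :]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _he_init(rng, n_in, (n_in, n_out))
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads[0] += self._x.T @ g
        self.grads[1] += g.sum(axis=0)
        return g @ self.W.T


class ReLU(Layer):
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class TemporalBlock(Layer):
    """Stacked dilated convolutions with a residual (skip) connection.

    ``out = relu(conv_stack(x) + shortcut(x))`` where the shortcut is the
    identity, or a 1x1 convolution when the channel width changes.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        dilation: int,
        n_layers: int,
        rng: np.random.Generator,
    ):
        self.convs: list[DilatedConv1d] = []
        self.relus: list[ReLU] = []
        c = c_in
        for _ in range(n_layers):
            self.convs.append(DilatedConv1d(c, c_out, kernel, dilation, rng))
            self.relus.append(ReLU())
            c = c_out
        self.shortcut = None if c_in == c_out else DilatedConv1d(c_in, c_out, 1, 1, rng)
        self.out_relu = ReLU()
        owners: list[Layer] = [*self.convs] + ([self.shortcut] if self.shortcut else [])
        self.params = [p for l in owners for p in l.params]
        self.grads = [g for l in owners for g in l.grads]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = x
        for i, conv in enumerate(self.convs):
            h = conv.forward(h, train)
            if i < len(self.convs) - 1:  # inner activations; last one after the add
                h = self.relus[i].forward(h, train)
        res = x if self.shortcut is None else self.shortcut.forward(x, train)
        return self.out_relu.forward(h + res, train)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.out_relu.backward(g)
        gres = g if self.shortcut is None else self.shortcut.backward(g)
        h = g
        for i in reversed(range(len(self.convs))):
            if i < len(self.convs) - 1:
                h = self.relus[i].backward(h)
            h = self.convs[i].backward(h)
        return h + gres


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = len(y)
    loss = float(-np.mean(np.log(np.maximum(p[np.arange(n), y], 1e-12))))
    g = p
    g[np.arange(n), y] -= 1.0
    return loss, (g / n).astype(np.float32)


class _GradOptimizer:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float):
        self.params, self.grads, self.lr = params, grads, lr

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def step(self) -> None:  # pragma: no cover
        raise NotImplementedError


class Adam(_GradOptimizer):
    def __init__(self, params, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, grads, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSprop(_GradOptimizer):
    def __init__(self, params, grads, lr, rho=0.9, eps=1e-8):
        super().__init__(params, grads, lr)
        self.rho, self.eps = rho, eps
        self.v = [np.zeros_like(p) for p in params]

    def step(self) -> None:
        for p, g, v in zip(self.params, self.grads, self.v):
            v[...] = self.rho * v + (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(v) + self.eps)


OPTIMIZERS = {"adam": Adam, "rmsprop": RMSprop}
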