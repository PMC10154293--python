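"""Minimal CPU layer library: the building blocks of the segmentation net.

All tensors are float32 and channels-last (NHWC).  Every layer implements
``forward(x, train)`` and ``backward(dout)``; forward caches whatever
backward needs, so layers are stateful and single-stream.  Convolutions
use the shift-and-add formulation -- one (C_in, C_out) matmul per kernel
tap on a shifted view of the padded input -- which keeps both passes on
contiguous BLAS calls without materialising an im2col matrix.

Correctness of every backward rule is pinned by central-difference
gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    """A learnable array plus its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)


class Conv2D:
    """Same-padding stride-1 convolution, kernel size 1 or 3, NHWC."""

    def __init__(self, name: str, c_in: int, c_out: int, k: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, c_in, c_out))
        self.k, self.pad = k, k // 2
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(f"{name}.W", w)
        self.b = Param(f"{name}.b", np.zeros(c_out))
        self._xp: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, _ = x.shape
        k, p = self.k, self.pad
        if k == 1:
            out = x.reshape(-1, self.c_in) @ self.W.value[0, 0] + self.b.value
            if train:
                self._xp = x
            return out.reshape(n, h, w, self.c_out)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        acc = np.tile(self.b.value, (n * h * w, 1)).astype(F32)
        for i in range(k):
            for j in range(k):
                sl = np.ascontiguousarray(xp[:, i:i + h, j:j + w, :]).reshape(-1, self.c_in)
                acc += sl @ self.W.value[i, j]
        if train:
            self._xp = xp
        return acc.reshape(n, h, w, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, f = dout.shape
        k, p = self.k, self.pad
        dmat = dout.reshape(-1, f)
        self.b.grad += dmat.sum(axis=0)
        if k == 1:
            x = self._xp
            self._xp = None
            self.W.grad[0, 0] += x.reshape(-1, self.c_in).T @ dmat
            return (dmat @ self.W.value[0, 0].T).reshape(n, h, w, self.c_in)
        xp = self._xp
        self._xp = None
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                sl = np.ascontiguousarray(xp[:, i:i + h, j:j + w, :]).reshape(-1, self.c_in)
                self.W.grad[i, j] += sl.T @ dmat
                dxp[:, i:i + h, j:j + w, :] += (dmat @ self.W.value[i, j].T).reshape(n, h, w, self.c_in)
        return dxp[:, p:-p, p:-p, :]


class BatchNorm2D:
    """Per-channel batch normalization with running inference statistics."""

    def __init__(self, name: str, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(f"{name}.gamma", np.ones(c))
        self.beta = Param(f"{name}.beta", np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(x.dtype)
        xhat = (x - mean) / std
        if train:
            self._cache = (xhat, std)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        self._cache = None
        m = dout.shape[0] * dout.shape[1] * dout.shape[2]
        dgamma = (dout * xhat).sum(axis=(0, 1, 2))
        dbeta = dout.sum(axis=(0, 1, 2))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        dx = (self.gamma.value / std) * (dout - dbeta / m - xhat * (dgamma / m))
        return dx.astype(dout.dtype)


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Sigmoid:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._out * (1.0 - self._out)


class MaxPool2:
    """2x2 max pooling, stride 2; requires even spatial dims."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        quads = np.stack([x[:, ::2, ::2], x[:, ::2, 1::2],
                          x[:, 1::2, ::2], x[:, 1::2, 1::2]])
        idx = quads.argmax(axis=0)
        out = np.take_along_axis(quads, idx[None], axis=0)[0]
        if train:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape, dtype=dout.dtype)
        idx = self._idx
        views = (dx[:, ::2, ::2], dx[:, ::2, 1::2], dx[:, 1::2, ::2], dx[:, 1::2, 1::2])
        for q, v in enumerate(views):
            v += dout * (idx == q)
        return dx


class UpsampleNearest2:
    """Nearest-neighbour x2 upsampling."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the channel (last) axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray,
                  class_weights: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Mean pixelwise categorical cross-entropy and its gradient w.r.t. logits.

    ``probs`` must be the softmax of the logits; the returned gradient is
    the usual ``(p - y) / n_pixels`` (weighted per class if requested).
    """
    n_pix = probs.shape[0] * probs.shape[1] * probs.shape[2]
    eps = 1e-9
    if class_weights is None:
        loss = -(onehot * np.log(probs + eps)).sum() / n_pix
        dlogits = (probs - onehot) / n_pix
    else:
        wmap = (onehot * class_weights).sum(axis=-1, keepdims=True)
        loss = -(wmap * onehot * np.log(probs + eps)).sum() / n_pix
        dlogits = wmap * (probs - onehot) / n_pix
    return float(loss), dlogits.astype(probs.dtype)


class Adam:
    """Adam optimizer with the standard default hyper-parameters."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
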