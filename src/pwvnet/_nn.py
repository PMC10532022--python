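"""Minimal CNN engine: layers, softmax cross-entropy, Adam.

Everything is float32 and NHWC.  Convolutions are realized as im2col + GEMM
(``numpy.lib.stride_tricks.sliding_window_view`` feeding one matmul per
layer per batch) with buffers reused across steps, since on a single CPU
the cost of this network is dominated by memory traffic over the first
convolution's 180x180x32 activation, not by arithmetic.  The input gradient
of a convolution is computed as a full convolution of the padded output
gradient with the flipped kernels; the first convolution of a network skips
its input gradient, which is never needed.  Max-pooling uses non-overlapping
windows via strided slices; on backward, ties inside a pooling window
duplicate the gradient to every maximum, which is exact whenever the tied
value is 0 (the common ReLU case -- those gradients die in the ReLU mask)
and otherwise affects only exactly-equal positive float32 activations.

Determinism: all weight initialization and data shuffling is driven by
explicit ``numpy.random.Generator`` instances, so a fixed seed gives
bitwise-identical runs on the same machine/BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Layer:
    """Base layer; subclasses fill ``params`` and matching ``grads``."""

    name: str = ""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, delta: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


def _buffer(cache: dict, key: str, shape: tuple[int, ...],
            dtype=F32) -> np.ndarray:
    buf = cache.get(key)
    if buf is None or buf.shape != shape:
        buf = np.empty(shape, dtype=dtype)
        cache[key] = buf
    return buf


class Conv2D(Layer):
    """'same' convolution, stride 1, optional fused ReLU."""

    def __init__(self, name: str, rng: np.random.Generator, c_in: int, c_out: int,
                 ksize: int = 3, relu: bool = True, input_grad: bool = True) -> None:
        super().__init__()
        self.name = name
        self.k, self.c_in, self.c_out = ksize, c_in, c_out
        self.relu = relu
        self.input_grad = input_grad
        fan_in = ksize * ksize * c_in
        w = _glorot(rng, (ksize, ksize, c_in, c_out), fan_in, ksize * ksize * c_out)
        self.params = [w, np.zeros(c_out, dtype=F32)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._bufs: dict[str, np.ndarray] = {}

    def _im2col(self, x: np.ndarray, c: int, key: str) -> np.ndarray:
        """(B*H*W, k*k*c) patch matrix, written into a reused buffer."""
        b, h, w = x.shape[:3]
        p = self.k // 2
        pad = _buffer(self._bufs, key + "_pad", (b, h + 2 * p, w + 2 * p, c))
        pad[:, :p], pad[:, h + p:] = 0, 0
        pad[:, :, :p], pad[:, :, w + p:] = 0, 0
        pad[:, p:h + p, p:w + p] = x
        win = sliding_window_view(pad, (self.k, self.k), axis=(1, 2))
        col = _buffer(self._bufs, key, (b * h * w, self.k * self.k * c))
        np.copyto(col.reshape(b, h, w, self.k, self.k, c),
                  win.transpose(0, 1, 2, 4, 5, 3))
        return col

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        b, h, w, _ = x.shape
        self._col = self._im2col(x, self.c_in, "col_x")
        y = _buffer(self._bufs, "out", (b * h * w, self.c_out))
        np.matmul(self._col, self.params[0].reshape(-1, self.c_out), out=y)
        y += self.params[1]
        if self.relu:
            np.maximum(y, 0, out=y)
        self._out = y
        return y.reshape(b, h, w, self.c_out)

    def backward(self, delta: np.ndarray) -> np.ndarray:
        b, h, w, _ = self._x_shape
        dflat = np.ascontiguousarray(delta).reshape(-1, self.c_out)
        if self.relu:
            mask = _buffer(self._bufs, "relu_mask", self._out.shape, dtype=bool)
            np.greater(self._out, 0, out=mask)
            dflat *= mask
        self.grads[0][...] = (self._col.T @ dflat).reshape(self.params[0].shape)
        self.grads[1][...] = dflat.sum(axis=0)
        if not self.input_grad:
            return dflat  # unused by caller (first layer)
        # full convolution of delta with spatially flipped, transposed kernels
        wflip = np.ascontiguousarray(
            self.params[0][::-1, ::-1].transpose(0, 1, 3, 2))  # (k,k,Cout,Cin)
        col_d = self._im2col(dflat.reshape(b, h, w, self.c_out),
                             self.c_out, "col_d")
        dx = _buffer(self._bufs, "dx", (b * h * w, self.c_in))
        np.matmul(col_d, wflip.reshape(-1, self.c_in), out=dx)
        return dx.reshape(b, h, w, self.c_in)


class MaxPool2D(Layer):
    """Non-overlapping pooling (size = stride); trailing rows/cols cropped."""

    def __init__(self, name: str, size: int = 4) -> None:
        super().__init__()
        self.name = name
        self.size = size
        self._bufs: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.size
        b, h, w, c = x.shape
        ho, wo = h // s, w // s
        self._x = x
        out = _buffer(self._bufs, "out", (b, ho, wo, c))
        np.copyto(out, x[:, 0:ho * s:s, 0:wo * s:s])
        for i in range(s):
            for j in range(s):
                if i or j:
                    np.maximum(out, x[:, i:ho * s:s, j:wo * s:s], out=out)
        self._out = out
        return out

    def backward(self, delta: np.ndarray) -> np.ndarray:
        s = self.size
        b, h, w, c = self._x.shape
        ho, wo = h // s, w // s
        dx = _buffer(self._bufs, "dx", (b, h, w, c))
        dx[...] = 0
        mask = _buffer(self._bufs, "mask", (b, ho, wo, c), dtype=bool)
        tmp = _buffer(self._bufs, "tmp", (b, ho, wo, c))
        for i in range(s):
            for j in range(s):
                sl = self._x[:, i:ho * s:s, j:wo * s:s]
                np.equal(sl, self._out, out=mask)
                np.multiply(delta, mask, out=tmp)
                dx[:, i:ho * s:s, j:wo * s:s] = tmp
        return dx


class Flatten(Layer):
    def __init__(self, name: str = "flatten") -> None:
        super().__init__()
        self.name = name

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return np.ascontiguousarray(x).reshape(x.shape[0], -1)

    def backward(self, delta: np.ndarray) -> np.ndarray:
        return delta.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer, optional ReLU."""

    def __init__(self, name: str, rng: np.random.Generator, n_in: int, n_out: int,
                 relu: bool = True) -> None:
        super().__init__()
        self.name = name
        self.relu = relu
        self.params = [_glorot(rng, (n_in, n_out), n_in, n_out),
                       np.zeros(n_out, dtype=F32)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.params[0] + self.params[1]
        if self.relu:
            np.maximum(y, 0, out=y)
        self._out = y
        return y

    def backward(self, delta: np.ndarray) -> np.ndarray:
        if self.relu:
            delta = delta * (self._out > 0)
        self.grads[0][...] = self._x.T @ delta
        self.grads[1][...] = delta.sum(axis=0)
        return delta @ self.params[0].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    eps = 1e-12
    return float(-(onehot * np.log(probs + eps)).sum() / probs.shape[0])


class Network:
    """A plain layer stack ending in logits; softmax applied at the loss."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(np.array(self.forward(np.asarray(x, dtype=F32))))

    def train_step(self, x: np.ndarray, onehot: np.ndarray,
                   optimizer: "Adam") -> tuple[float, np.ndarray]:
        """One forward/backward/update pass; returns (batch loss, probs)."""
        probs = softmax(self.forward(x))
        loss = cross_entropy(probs, onehot)
        delta = ((probs - onehot) / x.shape[0]).astype(F32)
        for layer in reversed(self.layers):
            delta = layer.backward(delta)
        optimizer.step()
        return loss, probs

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w


class Adam:
    """Adam with bias correction (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, net: Network, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in net.params]
        self.v = [np.zeros_like(p) for p in net.params]

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.net.params, self.net.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * np.square(g)
            p -= F32(lr_t) * m / (np.sqrt(v) + F32(self.eps))
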