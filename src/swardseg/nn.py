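"""Minimal CNN substrate: layers with explicit forward/backward, in NumPy.

Everything the segmentation network needs — stride-1 same-padding
convolutions (im2col), 2x2 max pooling, ReLU, batch normalisation, stride-1
average pooling with border-count normalisation, bilinear resizing — is
implemented here with hand-derived gradients, plus Xavier initialisation
and an Adam optimiser.  Tensors are NHWC float32.  Gradients are verified
against central finite differences in the test suite.

The engine is deliberately small: stride-1 convolutions only (all
down-sampling goes through pooling), single-use caches (one backward per
forward), no graph autodiff.  That is all an encoder-decoder segmentation
network requires, and it keeps the numerics auditable.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

FLOAT = np.float32


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=FLOAT)
        self.grad = np.zeros_like(self.value)
        self.name = name


def xavier_uniform(shape: tuple[int, ...], fan_in: int, fan_out: int,
                   rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(FLOAT)


class Layer:
    def params(self) -> list[Param]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padding stride-1 convolution, NHWC, odd kernel."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.cin, self.cout, self.k = cin, cout, k
        self.W = Param(xavier_uniform((k, k, cin, cout), k * k * cin, k * k * cout, rng), "W")
        self.b = Param(np.zeros(cout, dtype=FLOAT), "b")
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (N, H, W, C, k, k) -> (N, H, W, k, k, C)
        win = sliding_window_view(xp, (k, k), axis=(1, 2))
        return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        if self.k == 1:
            cols = x.reshape(-1, self.cin)
        else:
            cols = self._im2col(x, self.k).reshape(-1, self.k * self.k * self.cin)
        y = cols @ self.W.value.reshape(-1, self.cout) + self.b.value
        if train:
            self._cols, self._xshape = cols, x.shape
        return y.reshape(n, h, w, self.cout)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, _ = gy.shape
        gyf = gy.reshape(-1, self.cout)
        self.W.grad += (self._cols.T @ gyf).reshape(self.W.value.shape)
        self.b.grad += gyf.sum(axis=0)
        # gx = same-conv of gy with the spatially flipped, io-transposed kernel
        Wt = self.W.value[::-1, ::-1].transpose(0, 1, 3, 2)  # (k,k,cout,cin)
        if self.k == 1:
            gx = gyf @ Wt.reshape(self.cout, self.cin)
        else:
            cols = self._im2col(gy, self.k).reshape(-1, self.k * self.k * self.cout)
            gx = cols @ Wt.reshape(-1, self.cin)
        self._cols = None
        return gx.reshape(self._xshape)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class BatchNorm(Layer):
    """Per-channel batch normalisation over (N, H, W)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=FLOAT), "gamma")
        self.beta = Param(np.zeros(c, dtype=FLOAT), "beta")
        self.running_mean = np.zeros(c, dtype=FLOAT)
        self.running_var = np.ones(c, dtype=FLOAT)
        self.momentum, self.eps = momentum, eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv
            self._xhat, self._inv, self._m = xhat, inv, x.shape[0] * x.shape[1] * x.shape[2]
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv
        return (self.gamma.value * xhat + self.beta.value).astype(FLOAT)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv, m = self._xhat, self._inv, self._m
        self.gamma.grad += (gy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += gy.sum(axis=(0, 1, 2))
        gxhat = gy * self.gamma.value
        gx = (inv / m) * (
            m * gxhat
            - gxhat.sum(axis=(0, 1, 2))
            - xhat * (gxhat * xhat).sum(axis=(0, 1, 2))
        )
        self._xhat = None
        return gx.astype(FLOAT)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; input spatial dims must be even."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dims")
        v = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(
            n, h // 2, w // 2, c, 4
        )
        idx = v.argmax(axis=-1)
        y = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._xshape = idx, x.shape
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        g = np.zeros((n, h // 2, w // 2, c, 4), dtype=FLOAT)
        np.put_along_axis(g, self._idx[..., None], gy[..., None], axis=-1)
        gx = g.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, h, w, c)
        self._idx = None
        return gx


class AvgPoolSame(Layer):
    """k x k mean pooling, stride 1, same padding, border counts excluded.

    Border windows average only over in-bounds pixels, so a spatially
    constant field is an exact fixed point of the pooling.
    """

    def __init__(self, k: int):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.k = k
        self._counts: dict[tuple[int, int], np.ndarray] = {}

    def _count_map(self, h: int, w: int) -> np.ndarray:
        key = (h, w)
        if key not in self._counts:
            ones = np.ones((1, h, w, 1), dtype=FLOAT)
            self._counts[key] = self._window_sum(ones)
        return self._counts[key]

    def _window_sum(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        return win.sum(axis=(-2, -1)).astype(FLOAT)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        counts = self._count_map(x.shape[1], x.shape[2])
        return self._window_sum(x) / counts

    def backward(self, gy: np.ndarray) -> np.ndarray:
        counts = self._count_map(gy.shape[1], gy.shape[2])
        return self._window_sum(gy / counts)


def _resize_plan(n_in: int, n_out: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Half-pixel-centre bilinear mapping: (lower index, upper index, upper weight)."""
    src = (np.arange(n_out, dtype=np.float64) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(np.intp)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = (src - i0).astype(FLOAT)
    return i0, i1, w1


def bilinear_resize(x: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of an NHWC tensor (exact identity for equal sizes)."""
    h_out, w_out = out_hw
    n, h, w, c = x.shape
    if (h, w) == (h_out, w_out):
        return x
    yi0, yi1, wy = _resize_plan(h, h_out)
    xi0, xi1, wx = _resize_plan(w, w_out)
    top = x[:, yi0][:, :, xi0] * (1 - wx)[None, None, :, None] + x[:, yi0][:, :, xi1] * wx[None, None, :, None]
    bot = x[:, yi1][:, :, xi0] * (1 - wx)[None, None, :, None] + x[:, yi1][:, :, xi1] * wx[None, None, :, None]
    return (top * (1 - wy)[None, :, None, None] + bot * wy[None, :, None, None]).astype(FLOAT)


def bilinear_resize_grad(gy: np.ndarray, in_hw: tuple[int, int]) -> np.ndarray:
    """Adjoint of :func:`bilinear_resize`: scatter output grads to inputs."""
    h_in, w_in = in_hw
    n, h_out, w_out, c = gy.shape
    if (h_in, w_in) == (h_out, w_out):
        return gy
    yi0, yi1, wy = _resize_plan(h_in, h_out)
    xi0, xi1, wx = _resize_plan(w_in, w_out)
    gx = np.zeros((n, h_in, w_in, c), dtype=FLOAT)
    wy0, wy1 = (1 - wy), wy
    wx0, wx1 = (1 - wx), wx
    for iy, wyv in ((yi0, wy0), (yi1, wy1)):
        for ix, wxv in ((xi0, wx0), (xi1, wx1)):
            contrib = gy * wyv[None, :, None, None] * wxv[None, None, :, None]
            np.add.at(gx, (slice(None), iy[:, None], ix[None, :]), contrib)
    return gx


class Resize(Layer):
    """Bilinear resize to a target size fixed at forward time."""

    def __init__(self):
        self._in_hw: tuple[int, int] | None = None
        self.out_hw: tuple[int, int] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        assert self.out_hw is not None, "set out_hw before forward"
        if train:
            self._in_hw = (x.shape[1], x.shape[2])
        return bilinear_resize(x, self.out_hw)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return bilinear_resize_grad(gy, self._in_hw)


class Chain(Layer):
    """Sequential container."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.buffers().items():
                out[f"{i}.{k}"] = v
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


def conv_act_norm(cin: int, cout: int, k: int, rng: np.random.Generator,
                  norm: bool = True) -> Chain:
    """Conv -> ReLU -> BatchNorm block (activation before normalisation)."""
    layers: list[Layer] = [Conv2D(cin, cout, k, rng), ReLU()]
    if norm:
        layers.append(BatchNorm(cout))
    return Chain(layers)


class Adam:
    """Adam with bias correction (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Param], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
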