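"""Compact numpy neural-network core used by the embedding models.

Implements exactly the pieces the residual embedders and classifier heads
need — 2-D convolution (im2col), batch normalization, ReLU, max/global-average
pooling, linear layers, residual blocks — each with a hand-written backward
pass, plus SGD-with-momentum and Adam optimizers.  Layers store parameters as
:class:`Param` objects (data + grad); containers expose ``parameters()`` so
optimizers and checkpointing can treat a whole model uniformly.

All arithmetic is float32; image tensors are NCHW.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


class Layer:
    """Base class: forward caches what backward needs."""

    train_mode: bool = True

    def parameters(self) -> list[Param]:
        return []

    def train(self, mode: bool = True) -> None:
        self.train_mode = mode
        for child in getattr(self, "_children", []):
            child.train(mode)

    def eval(self) -> None:
        self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


# ---------------------------------------------------------------------------
# im2col helpers


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, k, k, oh, ow),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    cols = np.ascontiguousarray(view).reshape(n, c * k * k, oh * ow)
    return cols, oh, ow


def _col2im(
    cols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int, oh: int, ow: int
) -> np.ndarray:
    n, c, h, w = x_shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, oh, ow)
    for ki in range(k):
        for kj in range(k):
            xp[:, :, ki : ki + stride * oh : stride, kj : kj + stride * ow : stride] += cols[
                :, :, ki, kj
            ]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


class Conv2d(Layer):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        k: int,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = k, stride
        self.pad = k // 2 if pad is None else pad
        # He fan-out initialization, matching the usual residual-net recipe
        std = np.sqrt(2.0 / (out_ch * k * k))
        self.weight = Param(rng.normal(0.0, std, size=(out_ch, in_ch, k, k)))
        self.in_ch, self.out_ch = in_ch, out_ch

    def parameters(self) -> list[Param]:
        return [self.weight]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        self._cols = cols
        w2 = self.weight.data.reshape(self.out_ch, -1)
        out = np.matmul(w2, cols)  # (O,CKK) x (N,CKK,L) -> (N,O,L)
        self._oh, self._ow = oh, ow
        return out.reshape(x.shape[0], self.out_ch, oh, ow)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n = grad.shape[0]
        g2 = np.ascontiguousarray(grad.reshape(n, self.out_ch, -1))
        self.weight.grad += np.tensordot(g2, self._cols, axes=([0, 2], [0, 2])).reshape(
            self.weight.data.shape
        )
        w2 = self.weight.data.reshape(self.out_ch, -1)
        dcols = np.matmul(w2.T, g2)
        return _col2im(
            dcols, self._x_shape, self.k, self.stride, self.pad, self._oh, self._ow
        )


class BatchNorm2d(Layer):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.eps, self.momentum = eps, momentum

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.train_mode:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._istd[None, :, None, None]
        return (
            self.gamma.data[None, :, None, None] * self._xhat
            + self.beta.data[None, :, None, None]
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gamma.grad += (grad * self._xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.data[None, :, None, None]
        if not self.train_mode:
            return g * self._istd[None, :, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (g * self._xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (
            self._istd[None, :, None, None]
            * (g - sum_g / m - self._xhat * sum_gx / m)
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2d(Layer):
    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._x_shape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2), constant_values=-np.inf)
        cols, oh, ow = _im2col(
            xp.reshape(n * c, 1, *xp.shape[2:]), self.k, self.stride, 0
        )
        cols = cols.reshape(n, c, self.k * self.k, oh * ow)
        self._argmax = cols.argmax(axis=2)
        self._oh, self._ow, self._padded = oh, ow, xp.shape
        out = np.take_along_axis(cols, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]
        return out.reshape(n, c, oh, ow)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        oh, ow = self._oh, self._ow
        dcols = np.zeros((n, c, self.k * self.k, oh * ow), dtype=grad.dtype)
        np.put_along_axis(
            dcols, self._argmax[:, :, None, :], grad.reshape(n, c, 1, oh * ow), axis=2
        )
        dxp = _col2im(
            dcols.reshape(n * c, self.k * self.k, oh * ow),
            (n * c, 1, self._padded[2], self._padded[3]),
            self.k,
            self.stride,
            0,
            oh,
            ow,
        ).reshape(n, c, self._padded[2], self._padded[3])
        if self.pad:
            dxp = dxp[:, :, self.pad : self.pad + h, self.pad : self.pad + w]
        return dxp


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._hw = x.shape[2] * x.shape[3]
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / self._hw, self._shape).copy()


class Linear(Layer):
    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_dim)
        self.weight = Param(rng.normal(0.0, std, size=(in_dim, out_dim)))
        self.bias = Param(np.zeros(out_dim)) if bias else None

    def parameters(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        out = x @ self.weight.data
        if self.bias is not None:
            out = out + self.bias.data
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ grad
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data.T


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self._children = list(layers)

    def parameters(self) -> list[Param]:
        return [p for l in self._children for p in l.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self._children:
            x = l.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for l in reversed(self._children):
            grad = l.backward(grad)
        return grad


class BasicBlock(Layer):
    """Two 3x3 convolutions with an identity (or projected) shortcut."""

    expansion = 1

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, 1, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.relu2 = ReLU()
        if stride != 1 or in_ch != out_ch:
            self.shortcut: Layer | None = Sequential(
                Conv2d(in_ch, out_ch, 1, stride, pad=0, rng=rng), BatchNorm2d(out_ch)
            )
        else:
            self.shortcut = None
        self._children = [
            l
            for l in (self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu2, self.shortcut)
            if l is not None
        ]

    def parameters(self) -> list[Param]:
        return [p for l in self._children for p in l.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.relu1(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        sc = self.shortcut(x) if self.shortcut is not None else x
        return self.relu2(out + sc)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.relu2.backward(grad)
        d_branch = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(grad))))
        )
        d_skip = self.shortcut.backward(grad) if self.shortcut is not None else grad
        return d_branch + d_skip


class Bottleneck(Layer):
    """1x1 reduce, 3x3, 1x1 expand (x4) with shortcut."""

    expansion = 4

    def __init__(self, in_ch: int, mid_ch: int, stride: int, rng: np.random.Generator):
        out_ch = mid_ch * self.expansion
        self.conv1 = Conv2d(in_ch, mid_ch, 1, 1, pad=0, rng=rng)
        self.bn1 = BatchNorm2d(mid_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(mid_ch, mid_ch, 3, stride, rng=rng)
        self.bn2 = BatchNorm2d(mid_ch)
        self.relu2 = ReLU()
        self.conv3 = Conv2d(mid_ch, out_ch, 1, 1, pad=0, rng=rng)
        self.bn3 = BatchNorm2d(out_ch)
        self.relu3 = ReLU()
        if stride != 1 or in_ch != out_ch:
            self.shortcut: Layer | None = Sequential(
                Conv2d(in_ch, out_ch, 1, stride, pad=0, rng=rng), BatchNorm2d(out_ch)
            )
        else:
            self.shortcut = None
        self._children = [
            l
            for l in (
                self.conv1, self.bn1, self.relu1,
                self.conv2, self.bn2, self.relu2,
                self.conv3, self.bn3, self.relu3,
                self.shortcut,
            )
            if l is not None
        ]

    def parameters(self) -> list[Param]:
        return [p for l in self._children for p in l.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.relu1(self.bn1(self.conv1(x)))
        out = self.relu2(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        sc = self.shortcut(x) if self.shortcut is not None else x
        return self.relu3(out + sc)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.relu3.backward(grad)
        g = self.bn3.backward(grad)
        g = self.conv3.backward(g)
        g = self.relu2.backward(g)
        g = self.bn2.backward(g)
        g = self.conv2.backward(g)
        g = self.relu1.backward(g)
        g = self.bn1.backward(g)
        d_branch = self.conv1.backward(g)
        d_skip = self.shortcut.backward(grad) if self.shortcut is not None else grad
        return d_branch + d_skip


# ---------------------------------------------------------------------------
# Losses (value + input gradient)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(p[np.arange(n), labels] + 1e-12).mean()
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


# ---------------------------------------------------------------------------
# Optimizers


class SGD:
    def __init__(
        self,
        params: list[Param],
        lr: float = 0.01,
        momentum: float = 0.9,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._v):
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class Adam:
    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1**self._t
        bc2 = 1 - b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


# ---------------------------------------------------------------------------
# Checkpoint helpers


def get_state(model: Layer) -> list[np.ndarray]:
    state = [p.data.copy() for p in model.parameters()]
    state += [
        arr.copy()
        for l in _iter_layers(model)
        if isinstance(l, BatchNorm2d)
        for arr in (l.running_mean, l.running_var)
    ]
    return state


def set_state(model: Layer, state: list[np.ndarray]) -> None:
    params = model.parameters()
    for p, s in zip(params, state):
        p.data[...] = s
    bns = [l for l in _iter_layers(model) if isinstance(l, BatchNorm2d)]
    rest = state[len(params):]
    for bn, (m, v) in zip(bns, zip(rest[0::2], rest[1::2])):
        bn.running_mean[...] = m
        bn.running_var[...] = v


def _iter_layers(layer: Layer):
    yield layer
    for child in getattr(layer, "_children", []):
        yield from _iter_layers(child)
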