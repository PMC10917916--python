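"""Trainable layers with explicit forward/backward passes.

Each layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients into ``Param.grad`` during ``backward``.
Setting ``layer.record_output_grad = True`` makes ``backward`` keep the
gradient that arrived at the layer's *output* (used by Grad-CAM).
"""

from __future__ import annotations

import numpy as np

from . import ops


class Param:
    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    """Base class; stateless layers only need forward/backward."""

    record_output_grad = False

    def __init__(self):
        self.last_output: np.ndarray | None = None
        self.last_output_grad: np.ndarray | None = None

    def params(self):
        return iter(())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _maybe_record(self, dout: np.ndarray) -> None:
        if self.record_output_grad:
            self.last_output_grad = dout.copy()


class Conv2D(Layer):
    """2-D convolution, 'same' ceil-mode padding, He-normal init."""

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int,
                 rng: np.random.Generator, name: str = "conv"):
        super().__init__()
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        fan_in = k * k * in_ch
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k * k * in_ch, out_ch))
        self.w = Param(f"{name}.w", w.astype(np.float32))
        self.b = Param(f"{name}.b", np.zeros(out_ch, dtype=np.float32))

    def params(self):
        yield self.w
        yield self.b

    def forward(self, x, training=False):
        self._x_shape = x.shape
        xp = ops.pad_same(x, self.k, self.stride)
        self._xp_shape = xp.shape
        ho = -(-x.shape[1] // self.stride)
        wo = -(-x.shape[2] // self.stride)
        cols = ops.im2col(xp, self.k, self.stride, ho, wo)
        self._cols = cols if training else None
        out = cols.reshape(-1, cols.shape[-1]) @ self.w.value + self.b.value
        out = out.reshape(x.shape[0], ho, wo, self.out_ch)
        self.last_output = out
        return out

    def backward(self, dout):
        self._maybe_record(dout)
        b, ho, wo, _ = dout.shape
        dflat = dout.reshape(-1, self.out_ch)
        if self._cols is not None:  # eval-mode backward (Grad-CAM) skips w/b grads
            cols2d = self._cols.reshape(-1, self._cols.shape[-1])
            self.w.grad += cols2d.T @ dflat
            self.b.grad += dflat.sum(axis=0)
        dcols = dflat @ self.w.value.T
        dxp = ops.col2im(dcols.reshape(b, ho, wo, -1), self._xp_shape,
                         self.k, self.stride, ho, wo)
        return ops.unpad(dxp, self._x_shape[1], self._x_shape[2], self.k, self.stride)


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (B, H, W)."""

    def __init__(self, ch: int, name: str = "bn", momentum: float = 0.9,
                 eps: float = 1e-5):
        super().__init__()
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.gamma = Param(f"{name}.gamma", np.ones(ch, dtype=np.float32))
        self.beta = Param(f"{name}.beta", np.zeros(ch, dtype=np.float32))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def params(self):
        yield self.gamma
        yield self.beta

    def forward(self, x, training=False):
        axes = (0, 1, 2)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._cache = (xhat, inv, x.shape[0] * x.shape[1] * x.shape[2])
        self._training = training
        out = self.gamma.value * xhat + self.beta.value
        self.last_output = out
        return out

    def backward(self, dout):
        self._maybe_record(dout)
        axes = (0, 1, 2)
        if not self._training:
            # eval-mode backward only propagates dx (Grad-CAM); param grads
            # are meaningful in training mode only
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            return dout * self.gamma.value * inv
        xhat, inv, m = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value
        dx = (inv / m) * (m * dxhat - dxhat.sum(axis=axes)
                          - xhat * (dxhat * xhat).sum(axis=axes))
        return dx


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        out = x * self._mask
        self.last_output = out
        return out

    def backward(self, dout):
        self._maybe_record(dout)
        return dout * self._mask


class MaxPool2D(Layer):
    """Max pooling with 'same' ceil-mode padding (default 3x3, stride 1)."""

    def __init__(self, k: int = 3, stride: int = 1):
        super().__init__()
        self.k, self.stride = k, stride

    def forward(self, x, training=False):
        self._x_shape = x.shape
        xp = ops.pad_same(x, self.k, self.stride, fill=-np.inf)
        self._xp_shape = xp.shape
        ho = -(-x.shape[1] // self.stride)
        wo = -(-x.shape[2] // self.stride)
        out = np.full((x.shape[0], ho, wo, x.shape[3]), -np.inf, dtype=x.dtype)
        idx = np.zeros(out.shape, dtype=np.uint8)
        for ki in range(self.k):
            for kj in range(self.k):
                window = xp[:, ki : ki + ho * self.stride : self.stride,
                            kj : kj + wo * self.stride : self.stride, :]
                better = window > out
                out = np.where(better, window, out)
                idx[better] = ki * self.k + kj
        self._idx, self._ho, self._wo = idx, ho, wo
        self.last_output = out
        return out

    def backward(self, dout):
        self._maybe_record(dout)
        dxp = np.zeros(self._xp_shape, dtype=dout.dtype)
        for ki in range(self.k):
            for kj in range(self.k):
                mask = self._idx == ki * self.k + kj
                dxp[:, ki : ki + self._ho * self.stride : self.stride,
                    kj : kj + self._wo * self.stride : self.stride, :] += dout * mask
        return ops.unpad(dxp, self._x_shape[1], self._x_shape[2], self.k, self.stride)


class GlobalAvgPool(Layer):
    """Spatial mean per channel: (B,H,W,C) -> (B,C)."""

    def forward(self, x, training=False):
        self._hw = x.shape[1] * x.shape[2]
        self._shape = x.shape
        out = x.mean(axis=(1, 2))
        self.last_output = out
        return out

    def backward(self, dout):
        self._maybe_record(dout)
        b, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / self._hw,
                               (b, h, w, c)).astype(dout.dtype).copy()


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 name: str = "dense"):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim))
        self.w = Param(f"{name}.w", w.astype(np.float32))
        self.b = Param(f"{name}.b", np.zeros(out_dim, dtype=np.float32))

    def params(self):
        yield self.w
        yield self.b

    def forward(self, x, training=False):
        self._x = x
        out = x @ self.w.value + self.b.value
        self.last_output = out
        return out

    def backward(self, dout):
        self._maybe_record(dout)
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class Softmax(Layer):
    def forward(self, x, training=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=-1, keepdims=True)
        self._out = out
        self.last_output = out
        return out

    def backward(self, dout):
        self._maybe_record(dout)
        s = self._out
        return s * (dout - (dout * s).sum(axis=-1, keepdims=True))


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def params(self):
        for layer in self.layers:
            yield from layer.params()

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        self.last_output = x
        return x

    def backward(self, dout):
        self._maybe_record(dout)
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Residual(Layer):
    """body(x) + skip(x); skip is identity when ``projection`` is None."""

    def __init__(self, body: Layer, projection: Layer | None = None):
        super().__init__()
        self.body = body
        self.projection = projection

    def params(self):
        yield from self.body.params()
        if self.projection is not None:
            yield from self.projection.params()

    def forward(self, x, training=False):
        out = self.body.forward(x, training)
        skip = x if self.projection is None else self.projection.forward(x, training)
        out = out + skip
        self.last_output = out
        return out

    def backward(self, dout):
        self._maybe_record(dout)
        dx = self.body.backward(dout)
        if self.projection is None:
            return dx + dout
        return dx + self.projection.backward(dout)


class ParallelAdd(Layer):
    """Element-wise sum of two branches applied to the same input."""

    def __init__(self, branch_a: Layer, branch_b: Layer):
        super().__init__()
        self.branch_a = branch_a
        self.branch_b = branch_b

    def params(self):
        yield from self.branch_a.params()
        yield from self.branch_b.params()

    def forward(self, x, training=False):
        out = self.branch_a.forward(x, training) + self.branch_b.forward(x, training)
        self.last_output = out
        return out

    def backward(self, dout):
        self._maybe_record(dout)
        return self.branch_a.backward(dout) + self.branch_b.backward(dout)


def iter_layers(layer: Layer):
    """Depth-first iterator over all concrete layers."""
    yield layer
    for child_name in ("layers", "body", "projection", "branch_a", "branch_b"):
        child = getattr(layer, child_name, None)
        if child is None:
            continue
        if isinstance(child, list):
            for sub in child:
                yield from iter_layers(sub)
        else:
            yield from iter_layers(child)
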