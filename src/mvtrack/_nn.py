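"""Minimal CPU neural-network engine used by the landmark regressor.

A compact, dependency-free implementation of exactly the pieces the
coordinate-regression networks need: im2col convolutions, batch
normalization, ReLU, max/global-average pooling, fully-connected layers,
basic and bottleneck residual blocks, mean-squared-error loss and the Adam
optimizer.  Everything runs in float32 numpy and is deterministic given the
initialisation RNG and the data order, which is what makes the seeded
train/predict contract of :mod:`mvtrack.regressor` testable bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Layer:
    """Base layer: forward caches what backward needs; params/grads by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def modules(self):
        yield self


def _pad(x: np.ndarray, p: int, value: float = 0.0) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=value)


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 bias: bool = True) -> None:
        super().__init__()
        self.k, self.stride = k, stride
        self.pad_ = k // 2 if pad is None else pad
        rng = rng or np.random.default_rng()
        fan_in = c_in * k * k
        self.params["w"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, k, k)
        ).astype(F32)
        self.bias = bias
        if bias:
            self.params["b"] = np.zeros(c_out, dtype=F32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad_
        xp = _pad(x, p)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo, _, _ = win.shape
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        wmat = self.params["w"].reshape(self.params["w"].shape[0], -1)
        out = cols @ wmat.T
        if self.bias:
            out += self.params["b"]
        self._cache = (cols, x.shape, (ho, wo))
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, x_shape, (ho, wo) = self._cache
        n, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad_
        f = grad.shape[1]
        g = grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, f)
        wmat = self.params["w"].reshape(f, -1)
        self.grads["w"] = (g.T @ cols).reshape(self.params["w"].shape)
        if self.bias:
            self.grads["b"] = g.sum(axis=0)
        gcols = (g @ wmat).reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
        gxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += gcols[:, :, i, j]
        return gxp[:, :, p:p + h, p:p + w] if p else gxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(c, dtype=F32)
        self.params["beta"] = np.zeros(c, dtype=F32)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(F32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return (self.params["gamma"][None, :, None, None] * xhat
                + self.params["beta"][None, :, None, None]).astype(F32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n_eff = shape[0] * shape[2] * shape[3]
        self.grads["gamma"] = np.einsum("nchw,nchw->c", grad, xhat)
        self.grads["beta"] = grad.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = grad * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, F32(0.0))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, F32(0.0))


class MaxPool2d(Layer):
    def __init__(self, k: int, stride: int, pad: int = 0) -> None:
        super().__init__()
        self.k, self.stride, self.pad_ = k, stride, pad

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad_
        xp = _pad(x, p, value=-np.inf)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo, _, _ = win.shape
        flat = win.reshape(n, c, ho, wo, k * k)
        self._arg = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1).astype(F32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad_
        n, c, h, w = self._in_shape
        ho, wo = grad.shape[2:]
        gxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        ki, kj = np.divmod(self._arg, k)
        ni, ci, oi, oj = np.indices(grad.shape, sparse=False)
        np.add.at(gxp, (ni, ci, oi * s + ki, oj * s + kj), grad)
        return gxp[:, :, p:p + h, p:p + w] if p else gxp


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(
            grad[:, :, None, None] / (h * w), self._shape
        ).astype(F32)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["w"] = rng.normal(
            0.0, np.sqrt(2.0 / d_in), (d_out, d_in)
        ).astype(F32)
        self.params["b"] = np.zeros(d_out, dtype=F32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["w"] = grad.T @ self._x
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["w"]


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def modules(self):
        for layer in self.layers:
            yield from layer.modules()


class Residual(Layer):
    """y = relu(body(x) + shortcut(x)); identity shortcut unless given."""

    def __init__(self, body: Sequential, shortcut: Layer | None = None) -> None:
        super().__init__()
        self.body = body
        self.shortcut = shortcut
        self.relu = ReLU()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        main = self.body.forward(x, train)
        skip = self.shortcut.forward(x, train) if self.shortcut else x
        return self.relu.forward(main + skip, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.relu.backward(grad)
        g_main = self.body.backward(grad)
        g_skip = self.shortcut.backward(grad) if self.shortcut else grad
        return g_main + g_skip

    def modules(self):
        yield from self.body.modules()
        if self.shortcut is not None:
            yield from self.shortcut.modules()
        yield self.relu


# --------------------------------------------------------------------------
# architectures
# --------------------------------------------------------------------------

def _basic_block(c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator) -> Residual:
    body = Sequential(
        Conv2d(c_in, c_out, 3, stride=stride, rng=rng, bias=False),
        BatchNorm2d(c_out),
        ReLU(),
        Conv2d(c_out, c_out, 3, rng=rng, bias=False),
        BatchNorm2d(c_out),
    )
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = Sequential(
            Conv2d(c_in, c_out, 1, stride=stride, pad=0, rng=rng, bias=False),
            BatchNorm2d(c_out),
        )
    return Residual(body, shortcut)


def _bottleneck(c_in: int, c_mid: int, stride: int,
                rng: np.random.Generator) -> Residual:
    c_out = 4 * c_mid
    body = Sequential(
        Conv2d(c_in, c_mid, 1, pad=0, stride=1, rng=rng, bias=False),
        BatchNorm2d(c_mid),
        ReLU(),
        Conv2d(c_mid, c_mid, 3, stride=stride, rng=rng, bias=False),
        BatchNorm2d(c_mid),
        ReLU(),
        Conv2d(c_mid, c_out, 1, pad=0, rng=rng, bias=False),
        BatchNorm2d(c_out),
    )
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = Sequential(
            Conv2d(c_in, c_out, 1, pad=0, stride=stride, rng=rng, bias=False),
            BatchNorm2d(c_out),
        )
    return Residual(body, shortcut)


def build_tiny(input_size: tuple[int, int], rng: np.random.Generator,
               n_out: int = 4) -> Sequential:
    """Reduced-depth residual regressor for desk-scale training.

    Stride-4 stem and two strided basic residual blocks (12/24/48 channels)
    followed by a small fully-connected head regressing the four
    coordinates in pixels of the input grid.
    """
    trunk = Sequential(
        Conv2d(1, 12, 7, stride=4, rng=rng),
        ReLU(),
        _basic_block(12, 24, 2, rng),
        _basic_block(24, 48, 2, rng),
        Flatten(),
    )
    feat = trunk.forward(
        np.zeros((1, 1, *input_size), dtype=F32), train=False
    ).shape[1]
    return Sequential(trunk, Linear(feat, 96, rng=rng), ReLU(), Linear(96, n_out, rng=rng))


def build_resnet50(input_size: tuple[int, int], rng: np.random.Generator,
                   n_out: int = 4) -> Sequential:
    """The 50-layer bottleneck residual network with a 4-coordinate head."""
    layers: list[Layer] = [
        Conv2d(1, 64, 7, stride=2, rng=rng, bias=False),
        BatchNorm2d(64),
        ReLU(),
        MaxPool2d(3, 2, pad=1),
    ]
    c_in = 64
    for c_mid, blocks, first_stride in (
        (64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)
    ):
        for b in range(blocks):
            layers.append(_bottleneck(c_in, c_mid, first_stride if b == 0 else 1, rng))
            c_in = 4 * c_mid
    layers += [GlobalAvgPool(), Linear(2048, n_out, rng=rng)]
    return Sequential(*layers)


# --------------------------------------------------------------------------
# loss and optimizer
# --------------------------------------------------------------------------

def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all coordinates; returns (loss, grad)."""
    diff = (pred - target).astype(F32)
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    return loss, (2.0 / diff.size) * diff


class Adam:
    def __init__(self, model: Layer, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict[int, dict[str, tuple[np.ndarray, np.ndarray]]] = {}

    def step(self) -> None:
        self.t += 1
        for mod in self.model.modules():
            st = self.state.setdefault(id(mod), {})
            for name, p in mod.params.items():
                g = mod.grads.get(name)
                if g is None:
                    continue
                m, v = st.get(name, (np.zeros_like(p), np.zeros_like(p)))
                m = self.b1 * m + (1 - self.b1) * g
                v = self.b2 * v + (1 - self.b2) * g * g
                st[name] = (m, v)
                mhat = m / (1 - self.b1 ** self.t)
                vhat = v / (1 - self.b2 ** self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)


def get_parameters(model: Layer) -> list[np.ndarray]:
    """All parameter arrays (plus BN running stats) in a stable order."""
    out = []
    for mod in model.modules():
        for name in sorted(mod.params):
            out.append(mod.params[name])
        if isinstance(mod, BatchNorm2d):
            out.append(mod.running_mean)
            out.append(mod.running_var)
    return out


def set_parameters(model: Layer, arrays: list[np.ndarray]) -> None:
    it = iter(arrays)
    for mod in model.modules():
        for name in sorted(mod.params):
            mod.params[name] = np.asarray(next(it), dtype=F32)
        if isinstance(mod, BatchNorm2d):
            mod.running_mean = np.asarray(next(it), dtype=F32)
            mod.running_var = np.asarray(next(it), dtype=F32)
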