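"""NumPy neural-network layers with hand-derived backpropagation.

Layers operate on NHWC float arrays.  Each layer caches what its backward
pass needs during ``forward``; ``backward`` consumes the gradient of the
loss w.r.t. the layer output, stores parameter gradients in ``self.grads``
and returns one gradient per declared input.

Convolutions are stride-1 with ``same`` or ``valid`` padding, implemented by
im2col (``sliding_window_view``) plus tensor contraction; the input gradient
is the full correlation of the output gradient with the spatially flipped
kernel.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConstructionError, InvalidConfigError

_EPS_BN = 1e-5


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _act_forward(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "sigmoid":
        return _sigmoid(z)
    return z


def _act_backward(grad: np.ndarray, z: np.ndarray, a: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return grad * (z > 0)
    if activation == "sigmoid":
        return grad * a * (1.0 - a)
    return grad


def _pad_amount(kernel: int, padding: str) -> int:
    if padding == "same":
        if kernel % 2 == 0:
            raise InvalidConfigError("same padding requires an odd kernel size")
        return kernel // 2
    if padding == "valid":
        return 0
    raise InvalidConfigError(f"padding must be 'same' or 'valid', got {padding!r}")


def _windows(x: np.ndarray, kh: int, kw: int, ph: int, pw: int) -> np.ndarray:
    """(N, H', W', C, kh, kw) sliding windows of a zero-padded NHWC array."""
    if ph or pw:
        x = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    return sliding_window_view(x, (kh, kw), axis=(1, 2))


class Layer:
    """Base layer: a node in the network DAG."""

    kind = "base"

    def __init__(self, label: str):
        self.label = label
        self.inputs: list = []  # indices of producer layers, set at assembly
        self.params: dict = {}
        self.grads: dict = {}

    def out_shape(self, in_shapes):
        raise NotImplementedError

    def init_params(self, in_shapes, rng: np.random.Generator) -> None:
        pass

    def forward(self, xs, train_mode: bool, rng: np.random.Generator):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def spec(self) -> dict:
        return {"kind": self.kind, "label": self.label}


class Input(Layer):
    kind = "input"

    def __init__(self, shape, label="Input layer"):
        super().__init__(label)
        self.shape = tuple(shape)

    def out_shape(self, in_shapes):
        return self.shape

    def forward(self, xs, train_mode, rng):
        return xs[0]

    def backward(self, grad):
        return [grad]


class Conv2D(Layer):
    """Standard 2-D convolution (stride 1) with optional fused activation."""

    kind = "conv"

    def __init__(self, filters, kernel=(3, 3), padding="same", activation="none", label=None):
        super().__init__(label or f"Conv2D ({filters} filters, {kernel[0]} x {kernel[1]})")
        self.filters = int(filters)
        self.kernel = tuple(kernel)
        self.padding = padding
        self.activation = activation
        self.pad = (_pad_amount(kernel[0], padding), _pad_amount(kernel[1], padding))

    def out_shape(self, in_shapes):
        h, w, _ = in_shapes[0]
        kh, kw = self.kernel
        if self.padding == "valid":
            h, w = h - kh + 1, w - kw + 1
        return (h, w, self.filters)

    def init_params(self, in_shapes, rng):
        kh, kw = self.kernel
        c_in = in_shapes[0][2]
        fan_in = kh * kw * c_in
        self.params = {
            "w": rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kh, kw, c_in, self.filters)),
            "b": np.zeros(self.filters),
        }

    def forward(self, xs, train_mode, rng):
        (x,) = xs
        kh, kw = self.kernel
        win = _windows(x, kh, kw, *self.pad)
        z = np.tensordot(win, self.params["w"], axes=([4, 5, 3], [0, 1, 2])) + self.params["b"]
        a = _act_forward(z, self.activation)
        self._cache = (x, win, z, a)
        return a

    def backward(self, grad):
        x, win, z, a = self._cache
        g = _act_backward(grad, z, a, self.activation)
        w = self.params["w"]
        kh, kw = self.kernel
        ph, pw = self.pad
        self.grads = {
            "b": g.sum(axis=(0, 1, 2)),
            "w": np.tensordot(win, g, axes=([0, 1, 2], [0, 1, 2])).transpose(1, 2, 0, 3),
        }
        # input gradient: full correlation with the flipped kernel
        w_rot = w[::-1, ::-1].transpose(0, 1, 3, 2)  # (kh, kw, F, C)
        win_g = _windows(g, kh, kw, kh - 1, kw - 1)
        dxp = np.tensordot(win_g, w_rot, axes=([4, 5, 3], [0, 1, 2]))
        H, W = x.shape[1], x.shape[2]
        return [dxp[:, ph : ph + H, pw : pw + W, :]]


class DepthwiseConv2D(Layer):
    """Per-channel 3x3 convolution with optional batch norm then activation.

    Batch normalization (when enabled) normalizes the convolution output per
    channel before the activation, matching the usual depthwise-separable
    block layout.
    """

    kind = "depthwise_conv"

    def __init__(self, kernel=(3, 3), padding="same", batch_norm=True, activation="relu",
                 label=None, bn_momentum=0.9):
        super().__init__(label or f"DepthwiseConv2D ({kernel[0]} x {kernel[1]})")
        self.kernel = tuple(kernel)
        self.padding = padding
        self.batch_norm = bool(batch_norm)
        self.activation = activation
        self.bn_momentum = bn_momentum
        self.pad = (_pad_amount(kernel[0], padding), _pad_amount(kernel[1], padding))

    def out_shape(self, in_shapes):
        h, w, c = in_shapes[0]
        kh, kw = self.kernel
        if self.padding == "valid":
            h, w = h - kh + 1, w - kw + 1
        return (h, w, c)

    def init_params(self, in_shapes, rng):
        kh, kw = self.kernel
        c = in_shapes[0][2]
        self.params = {
            "w": rng.normal(0.0, np.sqrt(2.0 / (kh * kw)), size=(kh, kw, c)),
            "b": np.zeros(c),
        }
        if self.batch_norm:
            self.params["gamma"] = np.ones(c)
            self.params["beta"] = np.zeros(c)
        # running statistics are state, not trainable parameters
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, xs, train_mode, rng):
        (x,) = xs
        kh, kw = self.kernel
        win = _windows(x, kh, kw, *self.pad)
        z = np.einsum("nijcuv,uvc->nijc", win, self.params["w"], optimize=True) + self.params["b"]
        if self.batch_norm:
            if train_mode:
                mu = z.mean(axis=(0, 1, 2))
                var = z.var(axis=(0, 1, 2))
                m = self.bn_momentum
                self.running_mean = m * self.running_mean + (1 - m) * mu
                self.running_var = m * self.running_var + (1 - m) * var
            else:
                mu, var = self.running_mean, self.running_var
            std = np.sqrt(var + _EPS_BN)
            zhat = (z - mu) / std
            y = self.params["gamma"] * zhat + self.params["beta"]
            self._bn_cache = (z, mu, std, zhat, train_mode)
        else:
            y = z
            self._bn_cache = None
        a = _act_forward(y, self.activation)
        self._cache = (x, win, y, a)
        return a

    def backward(self, grad):
        x, win, y, a = self._cache
        g = _act_backward(grad, y, a, self.activation)
        self.grads = {}
        if self.batch_norm:
            z, mu, std, zhat, trained = self._bn_cache
            self.grads["gamma"] = (g * zhat).sum(axis=(0, 1, 2))
            self.grads["beta"] = g.sum(axis=(0, 1, 2))
            gz = g * self.params["gamma"]
            if trained:
                m = z.shape[0] * z.shape[1] * z.shape[2]
                dvar = (gz * (z - mu)).sum(axis=(0, 1, 2)) * (-0.5) / std**3
                dmu = -gz.sum(axis=(0, 1, 2)) / std + dvar * (-2.0 / m) * (z - mu).sum(
                    axis=(0, 1, 2)
                )
                g = gz / std + dvar * 2.0 * (z - mu) / m + dmu / m
            else:
                g = gz / std
        kh, kw = self.kernel
        ph, pw = self.pad
        self.grads["b"] = g.sum(axis=(0, 1, 2))
        self.grads["w"] = np.einsum("nijcuv,nijc->uvc", win, g, optimize=True)
        w_rot = self.params["w"][::-1, ::-1]
        win_g = _windows(g, kh, kw, kh - 1, kw - 1)
        dxp = np.einsum("nijcuv,uvc->nijc", win_g, w_rot, optimize=True)
        H, W = x.shape[1], x.shape[2]
        return [dxp[:, ph : ph + H, pw : pw + W, :]]


class Add(Layer):
    """Elementwise sum of two equally shaped feature maps (skip connection)."""

    kind = "add"

    def __init__(self, label="Add Layer (Skip connection)"):
        super().__init__(label)

    def out_shape(self, in_shapes):
        a, b = in_shapes
        if tuple(a) != tuple(b):
            raise ConstructionError(
                f"add-layer operands have mismatched shapes {tuple(a)} and {tuple(b)}"
            )
        return tuple(a)

    def forward(self, xs, train_mode, rng):
        return xs[0] + xs[1]

    def backward(self, grad):
        return [grad, grad]


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing rows/columns are dropped."""

    kind = "max_pool"

    def __init__(self, pool=(2, 2), label=None):
        super().__init__(label or f"MaxPooling2D ({pool[0]} x {pool[1]})")
        self.pool = tuple(pool)

    def out_shape(self, in_shapes):
        h, w, c = in_shapes[0]
        return (h // self.pool[0], w // self.pool[1], c)

    def forward(self, xs, train_mode, rng):
        (x,) = xs
        ph, pw = self.pool
        n, h, w, c = x.shape
        ho, wo = h // ph, w // pw
        xc = x[:, : ho * ph, : wo * pw, :]
        blocks = xc.reshape(n, ho, ph, wo, pw, c)
        out = blocks.max(axis=(2, 4))
        self._cache = (x.shape, blocks, out)
        return out

    def backward(self, grad):
        in_shape, blocks, out = self._cache
        ph, pw = self.pool
        n, ho, _, wo, _, c = blocks.shape
        mask = blocks == out[:, :, None, :, None, :]
        # split ties evenly so the gradient mass is conserved
        mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        db = mask * grad[:, :, None, :, None, :]
        dx = np.zeros(in_shape)
        dx[:, : ho * ph, : wo * pw, :] = db.reshape(n, ho * ph, wo * pw, c)
        return [dx]


class Dropout(Layer):
    """Inverted dropout: zero a fraction ``rate`` of units in train mode."""

    kind = "dropout"

    def __init__(self, rate=0.5, label=None):
        super().__init__(label or f"Dropout ({rate})")
        if not 0.0 <= rate < 1.0:
            raise InvalidConfigError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = float(rate)

    def out_shape(self, in_shapes):
        return tuple(in_shapes[0])

    def forward(self, xs, train_mode, rng):
        (x,) = xs
        if train_mode and self.rate > 0.0:
            mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
            self._mask = mask
            return x * mask
        self._mask = None
        return x

    def backward(self, grad):
        if self._mask is not None:
            return [grad * self._mask]
        return [grad]


class Flatten(Layer):
    kind = "flatten"

    def __init__(self, label="Flatten"):
        super().__init__(label)

    def out_shape(self, in_shapes):
        return (int(np.prod(in_shapes[0])),)

    def forward(self, xs, train_mode, rng):
        (x,) = xs
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return [grad.reshape(self._shape)]


class Dense(Layer):
    kind = "dense"

    def __init__(self, units, activation="none", label=None):
        name = {"sigmoid": "Sigmoid", "relu": "ReLU", "none": "Linear"}[activation]
        super().__init__(label or f"Dense ({units} unit, {name})")
        self.units = int(units)
        self.activation = activation

    def out_shape(self, in_shapes):
        return (self.units,)

    def init_params(self, in_shapes, rng):
        fan_in = in_shapes[0][0]
        self.params = {
            "w": rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, self.units)),
            "b": np.zeros(self.units),
        }

    def forward(self, xs, train_mode, rng):
        (x,) = xs
        z = x @ self.params["w"] + self.params["b"]
        a = _act_forward(z, self.activation)
        self._cache = (x, z, a)
        return a

    def backward(self, grad, from_preactivation=False):
        x, z, a = self._cache
        g = grad if from_preactivation else _act_backward(grad, z, a, self.activation)
        self.grads = {"w": x.T @ g, "b": g.sum(axis=0)}
        return [g @ self.params["w"].T]
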