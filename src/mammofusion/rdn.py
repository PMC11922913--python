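"""The Residual Depth-wise Network (RDN).

A compact binary classifier for enhanced mammograms.  The default
architecture is, in order:

    input (S, S, 3)
    Conv2D 32 @ 3x3 (same, ReLU)
    DepthwiseConv2D 3x3 (+ batch norm, ReLU)
    Conv2D 32 @ 1x1 (pointwise)
    Shortcut Conv2D 32 @ 1x1 (pointwise projection of the first conv output)
    Add (skip connection)
    Conv2D 64 @ 1x1 (pointwise, ReLU)
    DepthwiseConv2D 3x3 (+ batch norm, ReLU)
    Conv2D 64 @ 1x1 (pointwise, ReLU)
    Dropout 0.5
    Flatten
    Dense 1 (sigmoid)

Depthwise-separable convolutions (a per-channel spatial convolution followed
by a 1x1 cross-channel projection) replace full convolutions to keep the
parameter count small, and the additive shortcut gives the residual-learning
path.  The flatten stage feeds the full spatial map to the output unit; no
global pooling is applied.

The layer chain carries a machine-checkable shape table
(:func:`shape_table`), and :func:`forward` / :meth:`RDNNetwork.backward`
implement the network numerically with seeded weight initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _layers as L
from .errors import ConstructionError, InvalidConfigError, InvalidInputError

__all__ = [
    "RDNConfig",
    "RDNNetwork",
    "ShapeTable",
    "build_rdn",
    "shape_table",
    "forward",
    "count_parameters",
    # reusable layer types for custom assemblies
    "Input",
    "Conv2D",
    "DepthwiseConv2D",
    "Add",
    "MaxPool2D",
    "Dropout",
    "Flatten",
    "Dense",
]

Input = L.Input
Conv2D = L.Conv2D
DepthwiseConv2D = L.DepthwiseConv2D
Add = L.Add
MaxPool2D = L.MaxPool2D
Dropout = L.Dropout
Flatten = L.Flatten
Dense = L.Dense


@dataclass(frozen=True)
class RDNConfig:
    """Architecture parameters of the residual depth-wise network."""

    input_size: int = 128
    input_channels: int = 3
    block_widths: tuple = (32, 64)
    padding_mode: str = "same"
    use_batch_norm: bool = True
    dropout_rate: float = 0.5
    output_units: int = 1
    output_activation: str = "sigmoid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size < 8:
            raise InvalidConfigError(f"input_size must be >= 8, got {self.input_size}")
        if len(self.block_widths) == 0:
            raise ConstructionError("block_widths must be non-empty")
        widths = tuple(self.block_widths)
        if any(b >= a for a, b in zip(widths[1:], widths[:-1])):
            raise ConstructionError(
                f"block_widths must be strictly increasing, got {widths}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise InvalidConfigError(
                f"dropout_rate must be in [0, 1), got {self.dropout_rate}"
            )


@dataclass(frozen=True)
class ShapeTable:
    """Ordered (layer label, output shape) rows, one per layer."""

    rows: tuple  # of (label, shape tuple, kind)

    def labels(self):
        return [r[0] for r in self.rows]

    def shapes(self):
        return [r[1] for r in self.rows]

    def without(self, *kinds):
        """Rows excluding the given layer kinds (e.g. shape-transparent dropout)."""
        return ShapeTable(rows=tuple(r for r in self.rows if r[2] not in kinds))

    def to_text(self) -> str:
        width = max(len(r[0]) for r in self.rows) + 2
        lines = [f"{'Layer':<{width}}Output shape"]
        for label, shape, _ in self.rows:
            shown = shape if len(shape) > 1 else f"({shape[0]})"
            lines.append(f"{label:<{width}}{shown}")
        return "\n".join(lines)

    def to_json(self) -> list:
        return [{"layer": r[0], "output_shape": list(r[1])} for r in self.rows]


class RDNNetwork:
    """A shape-checked DAG of layers with seeded parameters.

    ``layers`` is an ordered list; each layer's ``inputs`` attribute holds the
    indices of its producer layers (the first layer must be an ``Input``).
    Shape consistency of the whole chain is verified at construction.
    """

    def __init__(self, layers, seed: int = 0, config: Optional[RDNConfig] = None):
        if not layers or not isinstance(layers[0], L.Input):
            raise ConstructionError("the first layer must be an Input layer")
        self.layers = list(layers)
        self.config = config
        self.seed = seed
        self._shapes = []
        for i, layer in enumerate(self.layers):
            in_shapes = [self._shapes[j] for j in layer.inputs]
            self._shapes.append(layer.out_shape(in_shapes))
        rng = np.random.default_rng(seed)
        for layer, in_shape_idx in zip(self.layers, range(len(self.layers))):
            in_shapes = [self._shapes[j] for j in layer.inputs]
            layer.init_params(in_shapes, rng)
        self._dropout_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        self.input_shape = self._shapes[0]

    # -- running ----------------------------------------------------------

    def forward(self, batch: np.ndarray, train_mode: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Per-image class-1 probability for a (n, S, S, C) batch in [0, 1]."""
        x = np.asarray(batch, dtype=float)
        expected = (None,) + tuple(self.input_shape)
        if x.ndim != 4 or tuple(x.shape[1:]) != tuple(self.input_shape):
            raise InvalidInputError(
                f"expected batch of shape (n, {', '.join(map(str, self.input_shape))}), "
                f"got {tuple(x.shape)}"
            )
        if rng is None:
            rng = self._dropout_rng
        self._outputs = []
        for layer in self.layers:
            xs = [self._outputs[j] for j in layer.inputs] or [x]
            self._outputs.append(layer.forward(xs, train_mode, rng))
        probs = self._outputs[-1]
        # keep the output in the open interval (0, 1)
        tiny = np.finfo(float).tiny
        return np.clip(probs, tiny, 1.0 - 1e-16).reshape(-1)

    def backward(self, grad_last: np.ndarray, from_preactivation: bool = False) -> None:
        """Backpropagate a gradient w.r.t. the final layer's output.

        With ``from_preactivation`` the gradient is taken w.r.t. the dense
        layer's pre-activation (the numerically stable path for the combined
        sigmoid / cross-entropy gradient ``p - y``).
        """
        grads = [None] * len(self.layers)
        grads[-1] = np.asarray(grad_last, dtype=float).reshape(self._outputs[-1].shape)
        for i in range(len(self.layers) - 1, 0, -1):
            g = grads[i]
            if g is None:
                continue
            layer = self.layers[i]
            if isinstance(layer, L.Dense) and i == len(self.layers) - 1:
                in_grads = layer.backward(g, from_preactivation=from_preactivation)
            else:
                in_grads = layer.backward(g)
            for j, gj in zip(layer.inputs, in_grads):
                grads[j] = gj if grads[j] is None else grads[j] + gj

    # -- parameter access --------------------------------------------------

    def parameters(self):
        """Flat list of (layer_index, name, array) trainable parameters."""
        return [
            (i, name, arr)
            for i, layer in enumerate(self.layers)
            for name, arr in layer.params.items()
        ]

    def gradients(self):
        return [
            (i, name, layer.grads[name])
            for i, layer in enumerate(self.layers)
            for name in layer.params
        ]

    def get_weights(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                state[f"{i}:{name}"] = arr.copy()
            if isinstance(layer, L.DepthwiseConv2D):
                state[f"{i}:running_mean"] = layer.running_mean.copy()
                state[f"{i}:running_var"] = layer.running_var.copy()
        return state

    def set_weights(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.array(state[f"{i}:{name}"])
            if isinstance(layer, L.DepthwiseConv2D):
                layer.running_mean = np.array(state[f"{i}:running_mean"])
                layer.running_var = np.array(state[f"{i}:running_var"])


def build_rdn(cfg: RDNConfig = None, seed: Optional[int] = None) -> RDNNetwork:
    """Assemble the residual depth-wise network for a configuration.

    The first block width forms the residual block (3x3 conv, depthwise,
    pointwise, 1x1 shortcut projection, add); each subsequent width appends a
    pointwise expansion, a depthwise 3x3 and a pointwise projection.
    """
    cfg = cfg or RDNConfig()
    if seed is None:
        seed = cfg.seed
    widths = tuple(cfg.block_widths)
    pad = cfg.padding_mode
    bn = cfg.use_batch_norm

    layers = []

    def add_layer(layer, *producer_indices):
        layer.inputs = list(producer_indices)
        layers.append(layer)
        return len(layers) - 1

    w0 = widths[0]
    i_in = add_layer(L.Input((cfg.input_size, cfg.input_size, cfg.input_channels)))
    i_conv = add_layer(
        L.Conv2D(w0, (3, 3), padding=pad, activation="relu",
                 label=f"Conv2D ({w0} filters, 3 x 3)"),
        i_in,
    )
    i_dw = add_layer(
        L.DepthwiseConv2D((3, 3), padding=pad, batch_norm=bn, activation="relu"),
        i_conv,
    )
    i_pw = add_layer(
        L.Conv2D(w0, (1, 1), padding=pad, activation="none",
                 label=f"Conv2D ({w0} filters, 1 x 1)"),
        i_dw,
    )
    i_short = add_layer(
        L.Conv2D(w0, (1, 1), padding=pad, activation="none",
                 label="Shortcut (Conv2D, 1 x 1)"),
        i_conv,
    )
    prev = add_layer(L.Add(), i_pw, i_short)

    for w in widths[1:]:
        prev = add_layer(
            L.Conv2D(w, (1, 1), padding=pad, activation="relu",
                     label=f"Conv2D ({w} filters, 1 x 1)"),
            prev,
        )
        prev = add_layer(
            L.DepthwiseConv2D((3, 3), padding=pad, batch_norm=bn, activation="relu"),
            prev,
        )
        prev = add_layer(
            L.Conv2D(w, (1, 1), padding=pad, activation="relu",
                     label=f"Conv2D ({w} filters, 1 x 1)"),
            prev,
        )

    if cfg.dropout_rate > 0.0:
        prev = add_layer(L.Dropout(cfg.dropout_rate), prev)
    prev = add_layer(L.Flatten(), prev)
    add_layer(
        L.Dense(cfg.output_units, activation=cfg.output_activation), prev
    )
    return RDNNetwork(layers, seed=seed, config=cfg)


def shape_table(net: RDNNetwork, input_size: Optional[int] = None) -> ShapeTable:
    """Analytically propagated output shape of every layer, in order.

    With ``input_size`` the table is recomputed for a different spatial side
    without rebuilding the network.
    """
    if input_size is None:
        shapes = net._shapes
    else:
        shapes = []
        for layer in net.layers:
            if isinstance(layer, L.Input):
                shapes.append((input_size, input_size, layer.shape[2]))
            else:
                shapes.append(layer.out_shape([shapes[j] for j in layer.inputs]))
    rows = tuple(
        (layer.label, tuple(shape), layer.kind)
        for layer, shape in zip(net.layers, shapes)
    )
    return ShapeTable(rows=rows)


def forward(net: RDNNetwork, batch: np.ndarray, train_mode: bool = False,
            rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Functional alias for :meth:`RDNNetwork.forward`."""
    return net.forward(batch, train_mode=train_mode, rng=rng)


def count_parameters(net: RDNNetwork) -> int:
    """Total number of trainable parameters in the network."""
    return int(sum(layer.n_params() for layer in net.layers))
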