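"""A small numpy layer engine with exact backpropagation.

Implements the layers the tile classifiers need — same-padded 3x3
convolution, 2x2 max/average pooling, dense, dropout, sequence reshaping,
LSTM (optionally bidirectional) — as forward/backward pairs over float64
arrays, plus a sequential :class:`Network` container and an Adam optimizer.
Gradients are derived analytically per layer and verified against central
finite differences in the test suite.

Array layout is channels-last: images are (batch, H, W, C), sequences are
(batch, time, features).
"""

from __future__ import annotations

from typing import Iterator, Sequence

import numpy as np

from . import nncore

__all__ = [
    "Layer",
    "Conv2D",
    "MaxPool2D",
    "AvgPool2D",
    "Flatten",
    "Dense",
    "Dropout",
    "SequenceReshape",
    "LSTM",
    "Bidirectional",
    "Network",
    "Adam",
]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: parameterized forward/backward with cached activations."""

    name: str = "layer"

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def init(self, rng: np.random.Generator) -> None:  # noqa: ARG002
        """Allocate parameters (layers without weights do nothing)."""

    def output_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        return in_shape

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


def _act_forward(kind: str, z: np.ndarray) -> np.ndarray:
    if kind == "linear":
        return z
    if kind == "relu":
        return np.maximum(0.0, z)
    raise ValueError(f"unsupported fused activation {kind!r}")


def _act_backward(kind: str, z: np.ndarray, dy: np.ndarray) -> np.ndarray:
    if kind == "linear":
        return dy
    if kind == "relu":
        return dy * (z > 0)
    raise ValueError(kind)


class Conv2D(Layer):
    """3x3 (or any odd k) convolution, stride 1, 'same' zero padding.

    Implemented as cross-correlation via im2col; with learned kernels this
    is equivalent to true convolution up to a kernel flip.
    """

    def __init__(self, in_maps: int, out_maps: int, kernel: int = 3,
                 activation: str = "relu", name: str = "conv"):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel must be odd for 'same' padding")
        self.in_maps, self.out_maps, self.k = in_maps, out_maps, kernel
        self.activation = activation
        self.name = name

    def init(self, rng: np.random.Generator) -> None:
        k, ci, co = self.k, self.in_maps, self.out_maps
        fan_in, fan_out = k * k * ci, k * k * co
        self.params = {
            "W": _glorot(rng, (k * k * ci, co), fan_in, fan_out),
            "b": np.zeros(co),
        }
        self.zero_grad()

    def output_shape(self, in_shape):
        h, w, c = in_shape
        if c != self.in_maps:
            raise ValueError(f"{self.name}: expected {self.in_maps} input maps, got {c}")
        return (*nncore.conv_output_shape((h, w), (self.k, self.k)), self.out_maps)

    def _im2col(self, xp: np.ndarray, h: int, w: int) -> np.ndarray:
        n = xp.shape[0]
        k, c = self.k, self.in_maps
        s0, s1, s2, s3 = xp.strides
        cols = np.lib.stride_tricks.as_strided(
            xp, (n, h, w, k, k, c), (s0, s1, s2, s1, s2, s3), writeable=False
        )
        return cols.reshape(n * h * w, k * k * c)

    def forward(self, x, train=False, rng=None):
        n, h, w, _ = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = self._im2col(xp, h, w)
        z = cols @ self.params["W"] + self.params["b"]
        self._cache = (cols, z, (n, h, w))
        return _act_forward(self.activation, z).reshape(n, h, w, self.out_maps)

    def backward(self, dy):
        cols, z, (n, h, w) = self._cache
        dz = _act_backward(self.activation, z, dy.reshape(n * h * w, self.out_maps))
        self.grads["W"] += cols.T @ dz
        self.grads["b"] += dz.sum(axis=0)
        dcols = (dz @ self.params["W"].T).reshape(n, h, w, self.k, self.k, self.in_maps)
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.in_maps))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p:p + h, p:p + w, :]


class _Pool2D(Layer):
    """Non-overlapping 2x2 pooling base."""

    def output_shape(self, in_shape):
        h, w, c = in_shape
        return (*nncore.pool_output_shape((h, w)), c)


class MaxPool2D(_Pool2D):
    name = "maxpool"

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max pooling needs even dimensions, got {h}x{w}")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        mask = xr == out[:, :, None, :, None, :]
        # split gradient evenly among tied maxima: deterministic and exact
        self._cache = (mask, mask.sum(axis=(2, 4), keepdims=True), x.shape)
        return out

    def backward(self, dy):
        mask, ties, shape = self._cache
        n, h, w, c = shape
        dyr = dy[:, :, None, :, None, :]
        return ((mask / ties) * dyr).reshape(n, h, w, c)


class AvgPool2D(_Pool2D):
    name = "avgpool"

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"average pooling needs even dimensions, got {h}x{w}")
        self._shape = x.shape
        return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(
            dy[:, :, None, :, None, :] / 4.0, (n, h // 2, 2, w // 2, 2, c)
        ).reshape(n, h, w, c)


class Flatten(Layer):
    name = "flatten"

    def output_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class SequenceReshape(Layer):
    """Reshape a flat feature vector into (time steps, input dimension).

    Row-major: step t carries features [t*id_dim, (t+1)*id_dim).
    """

    def __init__(self, ts: int, id_dim: int, name: str = "reshape"):
        super().__init__()
        if ts < 1 or id_dim < 1:
            raise ValueError("ts and id_dim must be >= 1")
        self.ts, self.id_dim = ts, id_dim
        self.name = name

    def output_shape(self, in_shape):
        (length,) = in_shape
        if self.ts * self.id_dim != length:
            raise ValueError(
                f"cannot reshape {length} features into ts={self.ts} x id={self.id_dim} "
                f"(product {self.ts * self.id_dim})"
            )
        return (self.ts, self.id_dim)

    def forward(self, x, train=False, rng=None):
        n, length = x.shape
        if self.ts * self.id_dim != length:
            raise ValueError(
                f"cannot reshape {length} features into ts={self.ts} x id={self.id_dim}"
            )
        return x.reshape(n, self.ts, self.id_dim)

    def backward(self, dy):
        return dy.reshape(dy.shape[0], -1)


class Dense(Layer):
    def __init__(self, in_units: int, out_units: int, activation: str = "linear",
                 name: str = "dense"):
        super().__init__()
        if in_units < 1 or out_units < 1:
            raise ValueError("unit counts must be >= 1")
        self.in_units, self.out_units = in_units, out_units
        self.activation = activation
        self.name = name

    def init(self, rng):
        self.params = {
            "W": _glorot(rng, (self.in_units, self.out_units), self.in_units, self.out_units),
            "b": np.zeros(self.out_units),
        }
        self.zero_grad()

    def output_shape(self, in_shape):
        (d,) = in_shape
        if d != self.in_units:
            raise ValueError(f"{self.name}: expected {self.in_units} inputs, got {d}")
        return (self.out_units,)

    def forward(self, x, train=False, rng=None):
        z = x @ self.params["W"] + self.params["b"]
        self._cache = (x, z)
        return _act_forward(self.activation, z)

    def backward(self, dy):
        x, z = self._cache
        dz = _act_backward(self.activation, z, dy)
        self.grads["W"] += x.T @ dz
        self.grads["b"] += dz.sum(axis=0)
        return dz @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout: active only in training passes; identity at eval."""

    def __init__(self, p: float, name: str = "dropout"):
        super().__init__()
        if not (0.0 <= p < 1.0):
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.name = name

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


def _sig(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTM(Layer):
    """Single LSTM layer with input, forget, candidate and output gates.

    Gate equations (conventional naming; sigmoid gates, tanh candidate):
        i = sig(x Wx_i + h' Wh_i + b_i)     input gate
        f = sig(x Wx_f + h' Wh_f + b_f)     forget gate
        g = tanh(x Wx_g + h' Wh_g + b_g)    candidate
        o = sig(x Wx_o + h' Wh_o + b_o)     output gate
        c = f * c' + i * g ;  h = o * tanh(c)
    Parameter count is 4·(h·(d+h)+h), matching
    :func:`histoclust.nncore.lstm_param_count`.
    """

    def __init__(self, input_dim: int, hidden: int, return_sequences: bool = False,
                 name: str = "lstm"):
        super().__init__()
        if input_dim < 1 or hidden < 1:
            raise ValueError("input_dim and hidden must be >= 1")
        self.input_dim, self.hidden = input_dim, hidden
        self.return_sequences = return_sequences
        self.name = name

    def init(self, rng):
        d, h = self.input_dim, self.hidden
        self.params = {
            "Wx": _glorot(rng, (d, 4 * h), d, 4 * h),
            "Wh": _glorot(rng, (h, 4 * h), h, 4 * h),
            "b": np.zeros(4 * h),
        }
        self.zero_grad()

    def output_shape(self, in_shape):
        t, d = in_shape
        if d != self.input_dim:
            raise ValueError(f"{self.name}: expected input dim {self.input_dim}, got {d}")
        return (t, self.hidden) if self.return_sequences else (self.hidden,)

    def forward(self, x, train=False, rng=None):
        n, t, d = x.shape
        h = self.hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        hs = np.zeros((n, t, h))
        h_prev = np.zeros((n, h))
        c_prev = np.zeros((n, h))
        cache = []
        for step in range(t):
            xt = x[:, step, :]
            a = xt @ Wx + h_prev @ Wh + b
            i = _sig(a[:, :h])
            f = _sig(a[:, h:2 * h])
            g = np.tanh(a[:, 2 * h:3 * h])
            o = _sig(a[:, 3 * h:])
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_new = o * tc
            cache.append((xt, h_prev, c_prev, i, f, g, o, tc))
            hs[:, step, :] = h_new
            h_prev, c_prev = h_new, c
        self._cache = (cache, x.shape)
        return hs if self.return_sequences else hs[:, -1, :]

    def backward(self, dy):
        cache, (n, t, d) = self._cache
        h = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dx = np.zeros((n, t, d))
        dh_next = np.zeros((n, h))
        dc_next = np.zeros((n, h))
        for step in reversed(range(t)):
            xt, h_prev, c_prev, i, f, g, o, tc = cache[step]
            if self.return_sequences:
                dh = dy[:, step, :] + dh_next
            else:
                dh = (dy if step == t - 1 else 0.0) + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di, dg, df = dc * g, dc * i, dc * c_prev
            dc_next = dc * f
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.grads["Wx"] += xt.T @ da
            self.grads["Wh"] += h_prev.T @ da
            self.grads["b"] += da.sum(axis=0)
            dx[:, step, :] = da @ Wx.T
            dh_next = da @ Wh.T
        return dx


class Bidirectional(Layer):
    """Run an LSTM forwards and backwards in time and sum the directions.

    With ``return_sequences`` the two direction outputs are aligned in time
    before summing; without it the two final states are summed.  Parameter
    count is exactly twice the wrapped layer's.
    """

    def __init__(self, forward_layer: LSTM, name: str = "bilstm"):
        super().__init__()
        self.fw = forward_layer
        self.bw = LSTM(forward_layer.input_dim, forward_layer.hidden,
                       return_sequences=forward_layer.return_sequences,
                       name=forward_layer.name + "_rev")
        self.name = name

    def init(self, rng):
        self.fw.init(rng)
        self.bw.init(rng)

    @property
    def params(self):  # type: ignore[override]
        return {**{"fw_" + k: v for k, v in self.fw.params.items()},
                **{"bw_" + k: v for k, v in self.bw.params.items()}}

    @params.setter
    def params(self, value):
        if value:  # only the empty initialization from Layer.__init__ is allowed
            raise AttributeError("set sub-layer params directly")

    @property
    def grads(self):  # type: ignore[override]
        return {**{"fw_" + k: v for k, v in self.fw.grads.items()},
                **{"bw_" + k: v for k, v in self.bw.grads.items()}}

    @grads.setter
    def grads(self, value):
        if value:
            raise AttributeError("set sub-layer grads directly")

    def zero_grad(self):
        self.fw.zero_grad()
        self.bw.zero_grad()

    def set_param(self, key: str, value: np.ndarray) -> None:
        side, name = key.split("_", 1)
        target = self.fw if side == "fw" else self.bw
        target.params[name] = value

    def output_shape(self, in_shape):
        return self.fw.output_shape(in_shape)

    def forward(self, x, train=False, rng=None):
        yf = self.fw.forward(x, train, rng)
        yb = self.bw.forward(x[:, ::-1, :], train, rng)
        if self.fw.return_sequences:
            return yf + yb[:, ::-1, :]
        return yf + yb

    def backward(self, dy):
        if self.fw.return_sequences:
            dxf = self.fw.backward(dy)
            dxb = self.bw.backward(dy[:, ::-1, :])
        else:
            dxf = self.fw.backward(dy)
            dxb = self.bw.backward(dy)
        return dxf + dxb[:, ::-1, :]


class Network:
    """A sequential network with seeded initialization and shape checking."""

    def __init__(self, layers: Sequence[Layer], input_shape: tuple[int, ...],
                 seed: int = 0, name: str = "network"):
        self.layers = list(layers)
        self.input_shape = tuple(input_shape)
        self.name = name
        self.seed = seed
        # deterministic per-layer initialization streams
        children = np.random.SeedSequence(seed).spawn(len(self.layers))
        shape = self.input_shape
        self.shapes: list[tuple[int, ...]] = [shape]
        for layer, child in zip(self.layers, children):
            layer.init(np.random.default_rng(child))
            shape = layer.output_shape(shape)
            self.shapes.append(shape)
        self.output_shape = shape

    # -- execution ---------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dscores: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dscores = layer.backward(dscores)
        return dscores

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def penultimate_features(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode activations feeding the decision layer."""
        for layer in self.layers[:-1]:
            x = layer.forward(x, train=False)
        return x

    # -- introspection -----------------------------------------------------
    def parameters(self) -> Iterator[tuple[Layer, str, np.ndarray]]:
        for layer in self.layers:
            for key in layer.params:
                yield layer, key, layer.params[key]

    def count_parameters(self) -> int:
        return sum(p.size for _, _, p in self.parameters())

    def summary(self) -> str:
        rows = [("layer", "output shape", "params")]
        for layer, shape in zip(self.layers, self.shapes[1:]):
            rows.append((layer.name, str(shape), str(layer.n_params)))
        rows.append(("total", str(self.output_shape), str(self.count_parameters())))
        widths = [max(len(r[i]) for r in rows) for i in range(3)]
        lines = ["  ".join(r[i].ljust(widths[i]) for i in range(3)) for r in rows]
        lines.insert(1, "-" * (sum(widths) + 4))
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save_weights(self, path) -> None:
        arrays = {
            f"{idx}:{key}": val
            for idx, layer in enumerate(self.layers)
            for key, val in layer.params.items()
        }
        np.savez(path, **arrays)

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            for name in data.files:
                idx_s, key = name.split(":", 1)
                layer = self.layers[int(idx_s)]
                if isinstance(layer, Bidirectional):
                    layer.set_param(key, data[name])
                else:
                    layer.params[key][...] = data[name]


class Adam:
    """Adam optimizer over a network's parameter tensors."""

    def __init__(self, net: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for idx, layer in enumerate(self.net.layers):
            grads = layer.grads
            for key, p in layer.params.items():
                g = grads[key]
                slot = (idx, key)
                if slot not in self.m:
                    self.m[slot] = np.zeros_like(p)
                    self.v[slot] = np.zeros_like(p)
                self.m[slot] = b1 * self.m[slot] + (1 - b1) * g
                self.v[slot] = b2 * self.v[slot] + (1 - b2) * g * g
                mhat = self.m[slot] / (1 - b1**self.t)
                vhat = self.v[slot] / (1 - b2**self.t)
                update = -self.lr * mhat / (np.sqrt(vhat) + self.eps)
                if isinstance(layer, Bidirectional):
                    layer.set_param(key, p + update)
                else:
                    layer.params[key][...] = p + update
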