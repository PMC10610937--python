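"""Minimal numpy neural-network engine for the 1-D architecture zoo.

Implements exactly the layer set the :mod:`fallnet.zoo` specs need — Conv1D
("same" padding, arbitrary stride), batch normalization, ReLU, max pooling,
LSTM, dropout, dense, global average pooling and residual bottleneck blocks —
with full reverse-mode gradients and an Adam optimizer.  Inputs are
``(batch, length, channels)`` arrays; every layer's backward pass is verified
against central-difference numerical gradients in the test suite.

The engine exists to make the pipeline trainable and exactly reproducible
with the scientific Python stack alone; it favors clarity and correctness
over speed, though convolutions are vectorized via im2col matmuls and the
problem sizes here (50-frame windows, ≤ a few hundred channels) keep CPU
training in the minutes range.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

from .errors import ConfigError
from . import zoo
from .zoo import BlockSpec, ModelSpec


class Layer:
    """Base layer: parameter dict + cached forward state for backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}  # non-trainable state

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """1-D convolution, "same" padding (TensorFlow convention), stride s."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng) -> None:
        super().__init__()
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        scale = math.sqrt(2.0 / (kernel * c_in))  # He initialization
        self.params["W"] = rng.normal(0.0, scale, size=(kernel * c_in, c_out))
        self.params["b"] = np.zeros(c_out)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, length, _ = x.shape
        out_len = -(-length // self.stride)
        pad = max((out_len - 1) * self.stride + self.kernel - length, 0)
        pl = pad // 2
        xp = np.pad(x, ((0, 0), (pl, pad - pl), (0, 0)))
        idx = np.arange(out_len)[:, None] * self.stride + np.arange(self.kernel)[None, :]
        cols = xp[:, idx, :]  # (B, out, k, C)
        xc = cols.reshape(b, out_len, self.kernel * self.c_in)
        self._cache = (xc, idx, xp.shape, pl, length)
        return xc @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xc, idx, xp_shape, pl, length = self._cache
        b, out_len, _ = dy.shape
        kc = self.kernel * self.c_in
        self.grads["W"] = xc.reshape(-1, kc).T @ dy.reshape(-1, self.c_out)
        self.grads["b"] = dy.sum(axis=(0, 1))
        dxc = (dy @ self.params["W"].T).reshape(b, out_len, self.kernel, self.c_in)
        dxp = np.zeros(xp_shape)
        np.add.at(dxp, (slice(None), idx), dxc)
        return dxp[:, pl : pl + length, :]


class BatchNorm(Layer):
    """Channel-wise batch norm over (batch, length); running stats for eval."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.buffers["running_mean"] = np.zeros(channels)
        self.buffers["running_var"] = np.ones(channels)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.buffers["running_mean"] = m * self.buffers["running_mean"] + (1 - m) * mean
            self.buffers["running_var"] = m * self.buffers["running_var"] + (1 - m) * var
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, x.shape, training)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, axes, shape, training = self._cache
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"]
        if not training:
            return dy * g * inv
        n = np.prod([shape[a] for a in axes])
        dxhat = dy * g
        return (
            inv / n * (n * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1D(Layer):
    """Valid max pooling with stride = pool size; trailing remainder dropped."""

    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, length, c = x.shape
        out = length // self.pool
        view = x[:, : out * self.pool, :].reshape(b, out, self.pool, c)
        am = view.argmax(axis=2)
        self._cache = (am, x.shape, out)
        return np.take_along_axis(view, am[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        am, shape, out = self._cache
        b, length, c = shape
        dview = np.zeros((b, out, self.pool, c))
        np.put_along_axis(dview, am[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros(shape)
        dx[:, : out * self.pool, :] = dview.reshape(b, out * self.pool, c)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._length = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, None, :], self._length, axis=1) / self._length


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng) -> None:
        super().__init__()
        scale = math.sqrt(2.0 / n_in)
        self.params["W"] = rng.normal(0.0, scale, size=(n_in, n_out))
        self.params["b"] = np.zeros(n_out)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng) -> None:
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LSTM(Layer):
    """Single LSTM layer (gate order i, f, g, o), zero initial state.

    Returns the full hidden sequence or only the final hidden state; backward
    is truncated-free BPTT over the whole window.
    """

    def __init__(self, c_in: int, hidden: int, rng, return_sequences: bool) -> None:
        super().__init__()
        self.c_in, self.hidden, self.return_sequences = c_in, hidden, return_sequences
        scale = math.sqrt(1.0 / c_in)
        self.params["Wx"] = rng.normal(0.0, scale, size=(c_in, 4 * hidden))
        self.params["Wh"] = rng.normal(0.0, math.sqrt(1.0 / hidden), size=(hidden, 4 * hidden))
        self.params["b"] = np.zeros(4 * hidden)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, t, _ = x.shape
        h = np.zeros((b, self.hidden))
        c = np.zeros((b, self.hidden))
        hs = np.empty((b, t, self.hidden))
        cache = []
        for step in range(t):
            z = x[:, step] @ self.params["Wx"] + h @ self.params["Wh"] + self.params["b"]
            i, f, g, o = np.split(z, 4, axis=1)
            i, f, o = _sigmoid(i), _sigmoid(f), _sigmoid(o)
            g = np.tanh(g)
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, step] = h
            cache.append((x[:, step], i, f, g, o, c_prev, tc, c))
        self._cache = (cache, hs, b, t)
        return hs if self.return_sequences else h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cache, hs, b, t = self._cache
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.empty((b, t, self.c_in))
        dh_next = np.zeros((b, self.hidden))
        dc_next = np.zeros((b, self.hidden))
        for step in reversed(range(t)):
            x_t, i, f, g, o, c_prev, tc, c = cache[step]
            dh = dh_next.copy()
            if self.return_sequences:
                dh += dy[:, step]
            elif step == t - 1:
                dh += dy
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            h_prev = hs[:, step - 1] if step > 0 else np.zeros((b, self.hidden))
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, step] = dz @ Wx.T
            dh_next = dz @ Wh.T
        self.grads["Wx"], self.grads["Wh"], self.grads["b"] = dWx, dWh, db
        return dx


class Residual(Layer):
    """Bottleneck residual block: main path + (identity | projection) shortcut,
    summed and passed through a final ReLU."""

    def __init__(self, main: list[Layer], shortcut: list[Layer]) -> None:
        super().__init__()
        self.main = main
        self.shortcut = shortcut  # empty list = identity shortcut

    def sublayers(self) -> list[Layer]:
        return self.main + self.shortcut

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = x
        for layer in self.main:
            y = layer.forward(y, training)
        s = x
        for layer in self.shortcut:
            s = layer.forward(s, training)
        self._mask = (y + s) > 0
        return (y + s) * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy * self._mask
        dmain = dy
        for layer in reversed(self.main):
            dmain = layer.backward(dmain)
        dshort = dy
        for layer in reversed(self.shortcut):
            dshort = layer.backward(dshort)
        return dmain + dshort


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

class Network:
    """A compiled :class:`~fallnet.zoo.ModelSpec`: ordered layers + softmax head."""

    def __init__(self, layers: list[Layer], spec: ModelSpec) -> None:
        self.layers = layers
        self.spec = spec

    # -- flat layer census (Residual blocks contribute their sublayers) ----
    def _all_layers(self) -> list[Layer]:
        out = []
        for layer in self.layers:
            if isinstance(layer, Residual):
                out.extend(layer.sublayers())
            else:
                out.append(layer)
        return out

    def parameter_count(self) -> int:
        """Trainable-parameter report: sizes of every allocated weight array."""
        return sum(p.size for l in self._all_layers() for p in l.params.values())

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(l, name) for l in self._all_layers() for name in l.params]

    # -- execution ---------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Class probabilities (softmax) in evaluation mode."""
        outs = []
        for start in range(0, len(x), batch_size):
            logits = self.forward(x[start : start + batch_size], training=False)
            outs.append(softmax(logits))
        return np.concatenate(outs, axis=0)

    # -- state -------------------------------------------------------------
    def state(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._all_layers()):
            for name, val in layer.params.items():
                out[f"{i}:{name}"] = val.copy()
            for name, val in layer.buffers.items():
                out[f"{i}:buf:{name}"] = val.copy()
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._all_layers()):
            for name in layer.params:
                layer.params[name] = state[f"{i}:{name}"].copy()
            for name in layer.buffers:
                layer.buffers[name] = state[f"{i}:buf:{name}"].copy()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(labels)
    loss = -float(np.log(p[np.arange(n), labels] + 1e-12).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def _conv_bn_relu(
    layers: list[Layer], c_in: int, c_out: int, k: int, stride: int,
    with_bn: bool, rng,
) -> int:
    layers.append(Conv1D(c_in, c_out, k, stride, rng))
    if with_bn:
        layers.append(BatchNorm(c_out))
    layers.append(ReLU())
    return c_out


def _build_bottleneck(block: BlockSpec, c_in: int, rng) -> tuple[Residual, int]:
    r, c, e = block.filters
    main: list[Layer] = []
    if block.slim:
        main += [Conv1D(c_in, c, block.kernel, block.stride, rng), BatchNorm(c), ReLU()]
    else:
        main += [Conv1D(c_in, r, 1, block.stride, rng), BatchNorm(r), ReLU()]
        main += [Conv1D(r, c, block.kernel, 1, rng), BatchNorm(c), ReLU()]
    main += [Conv1D(c, e, 1, 1, rng), BatchNorm(e)]  # final ReLU after the add
    if block.kind == zoo.CONVOLUTIONAL_BLOCK:
        shortcut: list[Layer] = [Conv1D(c_in, e, 1, block.stride, rng), BatchNorm(e)]
    else:
        shortcut = []
    return Residual(main, shortcut), e


def build_network(spec: ModelSpec, seed: int = 0) -> Network:
    """Compile a spec into a runnable network with seeded initialization."""
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    channels = spec.input_channels
    lstm_blocks = [i for i, b in enumerate(spec.blocks) if b.kind == zoo.LSTM_UNIT]
    for i, block in enumerate(spec.blocks):
        if block.kind in (zoo.CONV_UNIT, zoo.VGG_BLOCK):
            channels = _conv_bn_relu(
                layers, channels, block.filters, block.kernel, block.stride,
                block.with_bn, rng,
            )
            if block.pool_size:
                layers.append(MaxPool1D(block.pool_size))
            if block.dropout > 0:
                layers.append(Dropout(block.dropout, rng))
        elif block.kind == zoo.MAX_POOL:
            layers.append(MaxPool1D(block.pool_size or 2))
        elif block.kind in (zoo.IDENTITY_BLOCK, zoo.CONVOLUTIONAL_BLOCK):
            res, channels = _build_bottleneck(block, channels, rng)
            layers.append(res)
        elif block.kind == zoo.LSTM_UNIT:
            # the last LSTM emits only its final hidden state for the head
            return_sequences = i != lstm_blocks[-1]
            layers.append(LSTM(channels, block.filters, rng, return_sequences))
            channels = block.filters
            if block.dropout > 0:
                layers.append(Dropout(block.dropout, rng))
        else:  # pragma: no cover
            raise ConfigError(f"unhandled block kind {block.kind}")

    length = zoo.propagate_shapes(spec)[-1][0]
    if spec.head == zoo.FLATTEN_DENSE:
        layers.append(Flatten())
        feat = length * channels
        for h in spec.head_hidden:
            layers.append(Dense(feat, h, rng))
            layers.append(ReLU())
            if spec.dropout > 0:
                layers.append(Dropout(spec.dropout, rng))
            feat = h
        layers.append(Dense(feat, spec.n_classes, rng))
    elif spec.head == zoo.GAP_DENSE:
        layers.append(GlobalAvgPool())
        if spec.dropout > 0:
            layers.append(Dropout(spec.dropout, rng))
        layers.append(Dense(channels, spec.n_classes, rng))
    elif spec.head == zoo.LSTM_DENSE:
        layers.append(Dense(channels, spec.n_classes, rng))
    return Network(layers, spec)


class Adam:
    """Adam optimizer over a network's parameter census."""

    def __init__(
        self, network: Network, lr: float = 1e-3,
        beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7,
    ) -> None:
        self.network = network
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {id(l): {n: np.zeros_like(p) for n, p in l.params.items()}
                  for l in network._all_layers()}
        self.v = {id(l): {n: np.zeros_like(p) for n, p in l.params.items()}
                  for l in network._all_layers()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for layer in self.network._all_layers():
            for name, param in layer.params.items():
                grad = layer.grads.get(name)
                if grad is None:
                    continue
                m = self.m[id(layer)][name]
                v = self.v[id(layer)][name]
                m *= b1
                m += (1 - b1) * grad
                v *= b2
                v += (1 - b2) * grad**2
                param -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
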