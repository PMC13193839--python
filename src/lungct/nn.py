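"""Minimal NumPy neural-network layers with reverse-mode gradients.

Everything the hybrid classifier needs is implemented here: 2-D convolution
(im2col), max/average pooling, global average pooling, dense layers, ReLU,
inverted dropout, and a bidirectional GRU layer operating on the one-step
sequences the classification head uses.  All arrays are NHWC ``float32``.

Each layer exposes ``forward(x, training)`` / ``backward(dout)`` and carries
its parameters and gradients in dicts, so an optimizer can walk the layer
list generically.  A ``frozen`` flag excludes a layer from updates without
removing it from the backward pass (gradients must still flow through).
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

DTYPE = np.float32


class Layer:
    """Base class: parameter-free identity."""

    frozen = False

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


def _glorot_init(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape).astype(DTYPE)


class Conv2D(Layer):
    """3x3-style convolution, stride 1, symmetric zero padding, NHWC."""

    def __init__(self, in_ch, out_ch, ksize=3, pad=1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.ksize, self.pad = ksize, pad
        fan_in = ksize * ksize * in_ch
        self.params["W"] = _he_init(rng, (fan_in, out_ch), fan_in)
        self.params["b"] = np.zeros(out_ch, dtype=DTYPE)
        self.in_ch, self.out_ch = in_ch, out_ch

    def _cols(self, xp, oh, ow):
        k = self.ksize
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # win: (N, oh, ow, C, k, k) -> (N*oh*ow, C*k*k)
        return win.reshape(xp.shape[0] * oh * ow, self.in_ch * k * k)

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        if c != self.in_ch:
            raise ValidationError(f"expected {self.in_ch} channels, got {c}")
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        oh, ow = h + 2 * p - self.ksize + 1, w + 2 * p - self.ksize + 1
        # sliding window yields (..., C, k, k); match that order in W
        cols = self._cols(xp, oh, ow)
        out = cols @ self.params["W"] + self.params["b"]
        self._cache = (xp.shape, cols, (n, oh, ow))
        return out.reshape(n, oh, ow, self.out_ch)

    def backward(self, dout):
        xp_shape, cols, (n, oh, ow) = self._cache
        k = self.ksize
        dflat = dout.reshape(n * oh * ow, self.out_ch)
        self.grads["W"] = (cols.T @ dflat).astype(DTYPE)
        self.grads["b"] = dflat.sum(axis=0).astype(DTYPE)
        dcols = (dflat @ self.params["W"].T).reshape(n, oh, ow, self.in_ch, k, k)
        dxp = np.zeros(xp_shape, dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + oh, j : j + ow, :] += dcols[:, :, :, :, i, j]
        p = self.pad
        return dxp[:, p : xp_shape[1] - p, p : xp_shape[2] - p, :] if p else dxp


class MaxPool2(Layer):
    """2x2 max pooling, stride 2."""

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xr = xr.reshape(n, h // 2, w // 2, c, 4)
        idx = xr.argmax(axis=-1)
        self._cache = (x.shape, idx)
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        (n, h, w, c), idx = self._cache
        dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=DTYPE)
        np.put_along_axis(dxr, idx[..., None], dout[..., None].astype(DTYPE), axis=-1)
        dxr = dxr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dxr.reshape(n, h, w, c)


class AvgPoolDown(Layer):
    """f x f average pooling, stride f (cheap fixed downsampling)."""

    def __init__(self, factor):
        super().__init__()
        self.f = factor

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        f = self.f
        self._shape = x.shape
        return x.reshape(n, h // f, f, w // f, f, c).mean(axis=(2, 4))

    def backward(self, dout):
        n, h, w, c = self._shape
        f = self.f
        d = np.repeat(np.repeat(dout, f, axis=1), f, axis=2) / (f * f)
        return d.astype(DTYPE)


class GlobalAvgPool(Layer):
    """Collapse H and W to one pooled feature vector per image."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._shape
        return (np.ones((n, h, w, c), dtype=DTYPE) * dout[:, None, None, :] / (h * w))


class GlobalAvgMaxPool(Layer):
    """Concatenated global average and global max pooling: (n,h,w,c) -> (n,2c).

    The average half measures how much of the map responds (lesion area);
    the max half measures whether anything responds at all, which keeps a
    handful of strongly responding pixels visible after spatial collapse.
    """

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        flat = x.reshape(n, h * w, c)
        self._shape = x.shape
        self._argmax = flat.argmax(axis=1)
        return np.concatenate([flat.mean(axis=1), flat.max(axis=1)], axis=1)

    def backward(self, dout):
        n, h, w, c = self._shape
        davg = dout[:, :c]
        dmax = dout[:, c:]
        dx = (np.ones((n, h * w, c), dtype=DTYPE) * davg[:, None, :] / (h * w))
        np.put_along_axis(
            dx, self._argmax[:, None, :],
            np.take_along_axis(dx, self._argmax[:, None, :], axis=1) + dmax[:, None, :],
            axis=1,
        )
        return dx.reshape(n, h, w, c)


class BatchNorm(Layer):
    """Batch normalization over feature vectors (n, d).

    The pooled features of a dark, heavily masked image vary across samples
    by far less than their absolute scale; normalizing each feature across
    the batch puts those differences at unit scale, which is what the head
    needs to learn from them.  Running estimates of the batch moments are
    kept for inference and travel with the weights (they are stored in
    ``params`` but receive no gradient, so the optimizer skips them).
    """

    def __init__(self, dim, momentum=0.9):
        super().__init__()
        self.params["gamma"] = np.ones(dim, dtype=DTYPE)
        self.params["beta"] = np.zeros(dim, dtype=DTYPE)
        self.params["running_mean"] = np.zeros(dim, dtype=DTYPE)
        self.params["running_var"] = np.ones(dim, dtype=DTYPE)
        self.momentum = momentum
        self.eps = 1e-5
        self._seen = False

    def forward(self, x, training=False):
        # a frozen layer runs in inference mode: batch statistics are neither
        # used nor accumulated (standard frozen-batch-norm semantics)
        if training and not self.frozen:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            # seed the running stats with the first batch so that early
            # inference-mode evaluations are already on the right scale
            m = self.momentum if self._seen else 0.0
            self._seen = True
            self.params["running_mean"][...] = m * self.params["running_mean"] + (1 - m) * mu
            self.params["running_var"][...] = m * self.params["running_var"] + (1 - m) * var
        else:
            mu = self.params["running_mean"]
            var = self.params["running_var"]
        self._istd = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        self._xhat = ((x - mu) * self._istd).astype(DTYPE)
        self._batch_stats = training and not self.frozen
        return self._xhat * self.params["gamma"] + self.params["beta"]

    def backward(self, dout):
        xhat, istd = self._xhat, self._istd
        self.grads["gamma"] = (dout * xhat).sum(axis=0).astype(DTYPE)
        self.grads["beta"] = dout.sum(axis=0).astype(DTYPE)
        dxhat = dout * self.params["gamma"]
        if not self._batch_stats:
            return (dxhat * istd).astype(DTYPE)
        return (
            (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)) * istd
        ).astype(DTYPE)


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (n, h, w, c) feature maps."""

    def __init__(self, channels, momentum=0.9):
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.params["running_mean"] = np.zeros(channels, dtype=DTYPE)
        self.params["running_var"] = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = 1e-5
        self._seen = False

    def forward(self, x, training=False):
        axes = (0, 1, 2)
        if training and not self.frozen:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum if self._seen else 0.0
            self._seen = True
            self.params["running_mean"][...] = m * self.params["running_mean"] + (1 - m) * mu
            self.params["running_var"][...] = m * self.params["running_var"] + (1 - m) * var
        else:
            mu = self.params["running_mean"]
            var = self.params["running_var"]
        self._istd = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        self._xhat = ((x - mu) * self._istd).astype(DTYPE)
        self._batch_stats = training and not self.frozen
        return self._xhat * self.params["gamma"] + self.params["beta"]

    def backward(self, dout):
        xhat, istd = self._xhat, self._istd
        axes = (0, 1, 2)
        self.grads["gamma"] = (dout * xhat).sum(axis=axes).astype(DTYPE)
        self.grads["beta"] = dout.sum(axis=axes).astype(DTYPE)
        dxhat = dout * self.params["gamma"]
        if not self._batch_stats:
            return (dxhat * istd).astype(DTYPE)
        return (
            (dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes))
            * istd
        ).astype(DTYPE)


class Dense(Layer):
    def __init__(self, in_dim, out_dim, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["W"] = _glorot_init(rng, (in_dim, out_dim), in_dim, out_dim)
        self.params["b"] = np.zeros(out_dim, dtype=DTYPE)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = (self._x.T @ dout).astype(DTYPE)
        self.grads["b"] = dout.sum(axis=0).astype(DTYPE)
        return (dout @ self.params["W"].T).astype(DTYPE)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate, rng=None):
        super().__init__()
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x, training=False):
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class GRUCell:
    """Standard GRU cell parameters for one direction.

    Input, recurrent, and bias weights are kept for all three gates (update
    ``z``, reset ``r``, candidate ``h~``).  On a one-step sequence from a zero
    initial state the recurrence contributes nothing — the recurrent weights
    receive zero gradient — and the cell reduces to the gating form
    ``h = sigmoid(x Wz + bz) * tanh(x Wh + bh)``.
    """

    def __init__(self, in_dim, units, rng):
        self.units = units
        self.W = _glorot_init(rng, (in_dim, 3 * units), in_dim, 3 * units)
        self.U = _glorot_init(rng, (units, 3 * units), units, 3 * units)
        self.b = np.zeros(3 * units, dtype=DTYPE)

    def step_from_zero(self, x):
        """Forward one step with h_prev = 0; returns (h, cache)."""
        u = self.units
        pre = x @ self.W + self.b
        z = _sigmoid(pre[:, :u])
        h_cand = np.tanh(pre[:, 2 * u :])
        h = z * h_cand
        return h, (x, z, h_cand)

    def backward_from_zero(self, dh, cache):
        u = self.units
        x, z, h_cand = cache
        dz = dh * h_cand * z * (1.0 - z)
        dcand = dh * z * (1.0 - h_cand**2)
        dpre = np.zeros((x.shape[0], 3 * u), dtype=DTYPE)
        dpre[:, :u] = dz
        dpre[:, 2 * u :] = dcand
        dW = (x.T @ dpre).astype(DTYPE)
        db = dpre.sum(axis=0).astype(DTYPE)
        dx = (dpre @ self.W.T).astype(DTYPE)
        return dx, dW, db


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class BiGRU(Layer):
    """Bidirectional GRU over a length-1 sequence; outputs are concatenated.

    Input dropout (rate ``dropout``) is applied to the step input of each
    direction during training; recurrent dropout is accepted for interface
    completeness but has no effect on a single step from a zero state.
    """

    def __init__(self, in_dim, units, dropout=0.0, recurrent_dropout=0.0, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.units = units
        self.dropout = dropout
        self.recurrent_dropout = recurrent_dropout
        self.rng = rng
        self.fwd = GRUCell(in_dim, units, rng)
        self.bwd = GRUCell(in_dim, units, rng)
        self.params = {
            "Wf": self.fwd.W, "Uf": self.fwd.U, "bf": self.fwd.b,
            "Wb": self.bwd.W, "Ub": self.bwd.U, "bb": self.bwd.b,
        }

    def forward(self, x, training=False):
        if training and self.dropout > 0.0:
            keep = 1.0 - self.dropout
            self._drop = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
            xd = x * self._drop
        else:
            self._drop = None
            xd = x
        hf, self._cf = self.fwd.step_from_zero(xd)
        hb, self._cb = self.bwd.step_from_zero(xd)
        return np.concatenate([hf, hb], axis=1)

    def backward(self, dout):
        u = self.units
        dxf, dWf, dbf = self.fwd.backward_from_zero(dout[:, :u], self._cf)
        dxb, dWb, dbb = self.bwd.backward_from_zero(dout[:, u:], self._cb)
        self.grads = {
            "Wf": dWf, "bf": dbf, "Uf": np.zeros_like(self.fwd.U),
            "Wb": dWb, "bb": dbb, "Ub": np.zeros_like(self.bwd.U),
        }
        dx = dxf + dxb
        if self._drop is not None:
            dx = dx * self._drop
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray):
    """Mean categorical cross-entropy; returns (loss, dlogits)."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-(onehot * np.log(np.clip(p, 1e-12, None))).sum() / n)
    dlogits = ((p - onehot) / n).astype(DTYPE)
    return loss, dlogits


class Sequential:
    """A plain layer stack with shared forward/backward traversal."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def trainable_items(self):
        for li, layer in enumerate(self.layers):
            if layer.frozen:
                continue
            for name in layer.params:
                yield (li, name), layer

    def get_weights(self) -> dict:
        return {
            (li, name): p.copy()
            for li, layer in enumerate(self.layers)
            for name, p in layer.params.items()
        }

    def set_weights(self, weights: dict) -> None:
        for (li, name), value in weights.items():
            np.copyto(self.layers[li].params[name], value)


class Adam:
    """Adam with the standard bias-corrected moments."""

    def __init__(self, net: Sequential, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for key, layer in self.net.trainable_items():
            _, name = key
            g = layer.grads.get(name)
            if g is None:
                continue
            m = self.m.setdefault(key, np.zeros_like(layer.params[name]))
            v = self.v.setdefault(key, np.zeros_like(layer.params[name]))
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            layer.params[name] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
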