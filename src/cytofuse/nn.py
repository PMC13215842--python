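"""Minimal NumPy neural-network engine with manual backpropagation.

Exactly the layer set the pseudo-image CNN+ViT classifier needs: 3x3 same
convolution, batch normalization, 2x2 max pooling, inverted dropout, dense
layers, layer normalization, multi-head self-attention, and an Adam
optimizer.  Layers expose ``forward(x, train)`` / ``backward(dy)`` and keep
parameters and gradients in dicts so the optimizer can walk the whole
model.  Everything is float32 and fully deterministic given the seeds fed
to the stochastic layers.

Conventions: image tensors are NHWC; sequence tensors are (N, T, D).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "ReLU",
    "Conv2DSame",
    "BatchNorm",
    "MaxPool2x2",
    "Dropout",
    "Flatten",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
    "Sequential",
]

F32 = np.float32


class Layer:
    """Base class: parameterless identity."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(F32)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = {"W": _he_init(rng, (d_in, d_out), d_in), "b": np.zeros(d_out, F32)}

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.grads = {"W": x2.T @ dy2, "b": dy2.sum(axis=0)}
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(F32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(F32)


class Conv2DSame(Layer):
    """3x3 (or kxk, odd k) same-padding stride-1 convolution on NHWC."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        super().__init__()
        self.k = k
        self.params = {
            "W": _he_init(rng, (k, k, c_in, c_out), k * k * c_in),
            "b": np.zeros(c_out, F32),
        }

    def forward(self, x, train=False):
        k, p = self.k, self.k // 2
        n, h, w, cin = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))).astype(F32)
        self._shape = (n, h, w, cin)
        s0, s1, s2, s3 = xp.strides
        windows = np.lib.stride_tricks.as_strided(
            xp,
            shape=(n, h, w, k, k, cin),
            strides=(s0, s1, s2, s1, s2, s3),
            writeable=False,
        )
        self._cols = np.ascontiguousarray(windows).reshape(n * h * w, k * k * cin)
        out = self._cols @ self.params["W"].reshape(-1, self.params["W"].shape[-1])
        out += self.params["b"]
        return out.reshape(n, h, w, -1)

    def backward(self, dy):
        k = self.k
        n, h, w, cin = self._shape
        W = self.params["W"]
        cout = W.shape[-1]
        dy2 = dy.reshape(-1, cout)
        self.grads = {
            "W": (self._cols.T @ dy2).reshape(W.shape),
            "b": dy2.sum(axis=0),
        }
        dcols = (dy2 @ W.reshape(-1, cout).T).reshape(n, h, w, k, k, cin)
        p = k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, cin), F32)
        for di in range(k):
            for dj in range(k):
                dxp[:, di : di + h, dj : dj + w, :] += dcols[:, :, :, di, dj, :]
        return dxp[:, p : p + h, p : p + w, :]


class BatchNorm(Layer):
    """Channel-wise batch normalization over (N, H, W) or (N,) axes."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(c, F32), "beta": np.zeros(c, F32)}
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, F32)
        self.running_var = np.ones(c, F32)

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(F32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        self._xhat = ((x - mean) * self._inv_std).astype(F32)
        self._m = int(np.prod([x.shape[a] for a in axes]))
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        xhat, inv_std, m = self._xhat, self._inv_std, self._m
        self.grads = {"gamma": (dy * xhat).sum(axis=axes), "beta": dy.sum(axis=axes)}
        g = dy * self.params["gamma"]
        dx = (
            inv_std
            / m
            * (m * g - g.sum(axis=axes) - xhat * (g * xhat).sum(axis=axes))
        )
        return dx.astype(F32)


class MaxPool2x2(Layer):
    def forward(self, x, train=False):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xr = xr.reshape(n, h // 2, w // 2, c, 4)
        self._arg = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, h, w, c = self._in_shape
        dxr = np.zeros((n, h // 2, w // 2, c, 4), F32)
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None].astype(F32), axis=-1)
        dx = dxr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dx.reshape(n, h, w, c)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / keep
        return (x * self._mask).astype(F32)

    def backward(self, dy):
        return dy if self._mask is None else (dy * self._mask).astype(F32)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class LayerNorm(Layer):
    """Normalization over the last axis."""

    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(d, F32), "beta": np.zeros(d, F32)}
        self.eps = eps

    def forward(self, x, train=False):
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        self._xhat = ((x - mean) * self._inv_std).astype(F32)
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        xhat, inv_std = self._xhat, self._inv_std
        d = dy.shape[-1]
        axes = tuple(range(dy.ndim - 1))
        self.grads = {"gamma": (dy * xhat).sum(axis=axes), "beta": dy.sum(axis=axes)}
        g = dy * self.params["gamma"]
        dx = (
            inv_std
            / d
            * (
                d * g
                - g.sum(axis=-1, keepdims=True)
                - xhat * (g * xhat).sum(axis=-1, keepdims=True)
            )
        )
        return dx.astype(F32)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadSelfAttention(Layer):
    """Multi-head self-attention on (N, T, D) sequences."""

    def __init__(self, d: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if d % heads:
            raise ValueError("model dim must be divisible by head count")
        self.h, self.dh = heads, d // heads
        self.params = {}
        for name in ("Wq", "Wk", "Wv", "Wo"):
            self.params[name] = _he_init(rng, (d, d), d)
            self.params[name.replace("W", "b")] = np.zeros(d, F32)

    def _split(self, x):  # (N,T,D) -> (N,h,T,dh)
        n, t, _ = x.shape
        return x.reshape(n, t, self.h, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x):  # (N,h,T,dh) -> (N,T,D)
        n, h, t, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(n, t, h * dh)

    def forward(self, x, train=False):
        p = self.params
        self._x = x
        q = self._split(x @ p["Wq"] + p["bq"])
        k = self._split(x @ p["Wk"] + p["bk"])
        v = self._split(x @ p["Wv"] + p["bv"])
        att = softmax((q @ k.transpose(0, 1, 3, 2)) / np.sqrt(self.dh))
        ctx = self._merge(att @ v)
        self._cache = (q, k, v, att, ctx)
        return ctx @ p["Wo"] + p["bo"]

    def backward(self, dy):
        p = self.params
        x = self._x
        q, k, v, att, ctx = self._cache
        n, t, d = x.shape
        dy2 = dy.reshape(-1, d)
        self.grads = {"Wo": ctx.reshape(-1, d).T @ dy2, "bo": dy2.sum(axis=0)}
        dctx = self._split(dy @ p["Wo"].T)
        datt = dctx @ v.transpose(0, 1, 3, 2)
        dv = att.transpose(0, 1, 3, 2) @ dctx
        # softmax backward per row
        ds = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
        ds = ds / np.sqrt(self.dh)
        dq = ds @ k
        dk = ds.transpose(0, 1, 3, 2) @ q
        dx = np.zeros_like(x)
        x2 = x.reshape(-1, d)
        for name, grad in (("q", dq), ("k", dk), ("v", dv)):
            g = self._merge(grad).reshape(-1, d)
            self.grads[f"W{name}"] = x2.T @ g
            self.grads[f"b{name}"] = g.sum(axis=0)
            dx += (g @ p[f"W{name}"].T).reshape(n, t, d)
        return dx.astype(F32)


def softmax_cross_entropy(
    logits: np.ndarray, onehot: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean categorical cross-entropy; returns (loss, probabilities, dlogits)."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = float(-(onehot * np.log(np.clip(probs, 1e-12, None))).sum() / n)
    dlogits = ((probs - onehot) / n).astype(F32)
    return loss, probs, dlogits


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def walk(self):
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.walk()
            else:
                yield layer


class Adam:
    """Adam optimizer over a list of layers (walks their param dicts)."""

    def __init__(self, layers, lr: float = 1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                g = g.astype(F32)
                self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * g
                self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * g * g
                mhat = self.m[i][k] / b1t
                vhat = self.v[i][k] / b2t
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)
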