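"""Minimal NumPy neural-network layers with exact backpropagation.

Implements just what the frame-level sound-event detector needs: 2-D
convolution (same padding, im2col), ReLU, frequency-axis max pooling,
dropout, a bidirectional GRU over time, a time-distributed dense layer,
sigmoid outputs with (optionally positive-weighted) binary cross-entropy,
and Adam.  All layers support float32 or float64 and are deterministic
given a seeded ``numpy.random.Generator``; gradients are verified against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as sigmoid


class Layer:
    """Base: parameters in ``params``, matching gradients in ``grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self):
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (configurable) convolution with 'same' zero padding.

    Input/output layout: (batch, channels, time, freq).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel * kernel
        limit = np.sqrt(6.0 / (fan_in + c_out))
        self.params["W"] = rng.uniform(-limit, limit, (c_out, fan_in)).astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)
        self.zero_grad()

    def forward(self, x, train: bool = False):
        B, C, H, W = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * k * k)
        y = cols @ self.params["W"].T + self.params["b"]
        self._cache = (cols, (B, C, H, W))
        return np.ascontiguousarray(y.reshape(B, H, W, self.c_out).transpose(0, 3, 1, 2))

    def backward(self, dy):
        cols, (B, C, H, W) = self._cache
        k, p = self.k, self.k // 2
        dyf = dy.transpose(0, 2, 3, 1).reshape(B * H * W, self.c_out)
        self.grads["W"] += dyf.T @ cols
        self.grads["b"] += dyf.sum(axis=0)
        dcols = (dyf @ self.params["W"]).reshape(B, H, W, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + H, j : j + W] += dcols[:, :, :, :, i, j]
        return dxp[:, :, p : p + H, p : p + W]


class ReLU(Layer):
    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPoolFreq(Layer):
    """Max pooling over the frequency axis only; time resolution preserved."""

    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x, train: bool = False):
        B, C, H, W = x.shape
        f = self.factor
        if W % f:
            raise ValueError(f"frequency axis ({W}) not divisible by pool factor {f}")
        xr = x.reshape(B, C, H, W // f, f)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        B, C, H, W = self._shape
        f = self.factor
        dxr = np.zeros((B, C, H, W // f, f), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        return dxr.reshape(B, C, H, W)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x, train: bool = False):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class _GRUDirection(Layer):
    """Single-direction GRU; gate order (reset, update, candidate)."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.d_in, self.hidden = d_in, hidden
        lim_x = np.sqrt(6.0 / (d_in + hidden))
        lim_h = np.sqrt(6.0 / (2 * hidden))
        self.params["Wx"] = rng.uniform(-lim_x, lim_x, (d_in, 3 * hidden)).astype(dtype)
        self.params["Wh"] = rng.uniform(-lim_h, lim_h, (hidden, 3 * hidden)).astype(dtype)
        self.params["bx"] = np.zeros(3 * hidden, dtype=dtype)
        self.params["bh"] = np.zeros(hidden, dtype=dtype)
        self.zero_grad()

    def forward(self, x, train: bool = False):
        B, T, _ = x.shape
        H = self.hidden
        Wx, Wh, bx, bh = (self.params[k] for k in ("Wx", "Wh", "bx", "bh"))
        gi_all = x @ Wx + bx  # (B, T, 3H)
        h = np.zeros((B, H), dtype=x.dtype)
        out = np.empty((B, T, H), dtype=x.dtype)
        R = np.empty((B, T, H), dtype=x.dtype)
        Z = np.empty((B, T, H), dtype=x.dtype)
        N = np.empty((B, T, H), dtype=x.dtype)
        GHN = np.empty((B, T, H), dtype=x.dtype)
        Hprev = np.empty((B, T, H), dtype=x.dtype)
        for t in range(T):
            gh = h @ Wh
            gi = gi_all[:, t]
            r = sigmoid(gi[:, :H] + gh[:, :H])
            z = sigmoid(gi[:, H : 2 * H] + gh[:, H : 2 * H])
            ghn = gh[:, 2 * H :] + bh
            n = np.tanh(gi[:, 2 * H :] + r * ghn)
            Hprev[:, t] = h
            R[:, t], Z[:, t], N[:, t], GHN[:, t] = r, z, n, ghn
            h = (1.0 - z) * n + z * h
            out[:, t] = h
        self._cache = (x, R, Z, N, GHN, Hprev)
        return out

    def backward(self, dout):
        x, R, Z, N, GHN, Hprev = self._cache
        B, T, D = x.shape
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        WhT = np.ascontiguousarray(Wh.T)
        dgi_all = np.empty((B, T, 3 * H), dtype=x.dtype)
        dgh_all = np.empty((B, T, 3 * H), dtype=x.dtype)
        dh_next = np.zeros((B, H), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            r, z, n, ghn, h_prev = R[:, t], Z[:, t], N[:, t], GHN[:, t], Hprev[:, t]
            dh = dout[:, t] + dh_next
            dz = dh * (h_prev - n) * z * (1.0 - z)
            dn = dh * (1.0 - z) * (1.0 - n * n)  # grad w.r.t. tanh pre-activation
            dr = dn * ghn * r * (1.0 - r)
            dgi = dgi_all[:, t]
            dgh = dgh_all[:, t]
            dgi[:, :H] = dr
            dgi[:, H : 2 * H] = dz
            dgi[:, 2 * H :] = dn
            dgh[:, :H] = dr
            dgh[:, H : 2 * H] = dz
            dgh[:, 2 * H :] = dn * r
            dh_next = dh * z + dgh @ WhT
        x2 = x.reshape(B * T, D)
        dgi2 = dgi_all.reshape(B * T, 3 * H)
        dgh2 = dgh_all.reshape(B * T, 3 * H)
        self.grads["Wx"] += x2.T @ dgi2
        self.grads["bx"] += dgi2.sum(axis=0)
        self.grads["Wh"] += Hprev.reshape(B * T, H).T @ dgh2
        self.grads["bh"] += dgh_all[:, :, 2 * H :].sum(axis=(0, 1))
        return dgi_all @ Wx.T


class BiGRU(Layer):
    """Bidirectional GRU; output concatenates both directions (2*hidden)."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.fwd = _GRUDirection(d_in, hidden, rng, dtype)
        self.bwd = _GRUDirection(d_in, hidden, rng, dtype)

    @property
    def children(self):
        return [self.fwd, self.bwd]

    def zero_grad(self):
        self.fwd.zero_grad()
        self.bwd.zero_grad()

    def forward(self, x, train: bool = False):
        yf = self.fwd.forward(x, train)
        yb = self.bwd.forward(x[:, ::-1], train)[:, ::-1]
        return np.concatenate([yf, yb], axis=2)

    def backward(self, dy):
        H = self.fwd.hidden
        dxf = self.fwd.backward(np.ascontiguousarray(dy[:, :, :H]))
        dxb = self.bwd.backward(np.ascontiguousarray(dy[:, ::-1, H:]))[:, ::-1]
        return dxf + dxb


class Dense(Layer):
    """Time-distributed affine layer: (..., d_in) -> (..., d_out)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.params["W"] = rng.uniform(-limit, limit, (d_in, d_out)).astype(dtype)
        self.params["b"] = np.zeros(d_out, dtype=dtype)
        self.zero_grad()

    def forward(self, x, train: bool = False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.grads["W"] += x2.T @ dy2
        self.grads["b"] += dy2.sum(axis=0)
        return dy @ self.params["W"].T


def bce_loss(probs: np.ndarray, targets: np.ndarray, pos_weight=None,
             eps: float = 1e-7) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits.

    ``pos_weight`` (per-class vector) scales the positive term, countering
    class imbalance; None means unweighted.
    """
    p = np.clip(probs, eps, 1.0 - eps)
    y = targets.astype(p.dtype)
    if pos_weight is None:
        w = np.ones(p.shape[-1], dtype=p.dtype)
    else:
        w = np.asarray(pos_weight, dtype=p.dtype)
    loss = -(w * y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    n = p.size
    dlogits = ((1.0 + (w - 1.0) * y) * p - w * y) / n
    return float(loss.mean()), dlogits.astype(p.dtype)


class Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[li][k] = self.b1 * self.m[li][k] + (1.0 - self.b1) * g
                self.v[li][k] = self.b2 * self.v[li][k] + (1.0 - self.b2) * g * g
                mhat = self.m[li][k] / b1t
                vhat = self.v[li][k] / b2t
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def flatten_layers(layers):
    """Expand composite layers (BiGRU) into parameter-holding leaves."""
    out = []
    for l in layers:
        if hasattr(l, "children"):
            out.extend(l.children)
        else:
            out.append(l)
    return out
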