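"""A small NumPy neural-network engine (float64, CPU).

Layers follow a functional caching convention so the same layer object can
be applied several times per forward pass (needed for shared-weight,
time-distributed application and for recurrent cells):

    out, cache = layer.forward(x, training)
    dx = layer.backward(dout, cache)   # accumulates parameter gradients

All tensors are channels-last: (batch, N, H, W, C) for grid data.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x):
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Conv3D:
    """3-D convolution over (N, H, W) with same padding, stride 1.

    Odd kernel sizes only (1 or 3 in this architecture). Implemented with
    im2col so forward and both backward passes are single matmuls.
    """

    def __init__(self, cin: int, cout: int, kernel: tuple[int, int, int],
                 rng: np.random.Generator, bias: bool = True,
                 init_scale: float | None = None):
        self.cin, self.cout, self.kernel = cin, cout, tuple(kernel)
        if any(k % 2 == 0 for k in self.kernel):
            raise ValueError("same-padding requires odd kernel sizes")
        k_prod = int(np.prod(self.kernel))
        fan_in = k_prod * cin
        scale = init_scale if init_scale is not None else np.sqrt(2.0 / fan_in)
        self.W = Param(rng.standard_normal((fan_in, cout)) * scale)
        self.b = Param(np.zeros(cout)) if bias else None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def _patches(self, x):
        kd, kh, kw = self.kernel
        pd, ph, pw = kd // 2, kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (pd, pd), (ph, ph), (pw, pw), (0, 0)))
        view = np.lib.stride_tricks.sliding_window_view(xp, self.kernel,
                                                        axis=(1, 2, 3))
        # view: (B, N, H, W, C, kd, kh, kw) -> (B, N, H, W, kd, kh, kw, C)
        return np.ascontiguousarray(np.moveaxis(view, 4, 7))

    def forward(self, x, training=False):
        if x.shape[-1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[-1]}")
        b, d, h, w, _ = x.shape
        patches = self._patches(x).reshape(b * d * h * w, -1)
        out = patches @ self.W.value
        if self.b is not None:
            out += self.b.value
        return out.reshape(b, d, h, w, self.cout), (patches, x.shape)

    def backward(self, dout, cache):
        patches, xshape = cache
        b, d, h, w, _ = xshape
        dmat = dout.reshape(-1, self.cout)
        self.W.grad += patches.T @ dmat
        if self.b is not None:
            self.b.grad += dmat.sum(axis=0)
        dpatch = (dmat @ self.W.value.T).reshape(
            b, d, h, w, *self.kernel, self.cin
        )
        kd, kh, kw = self.kernel
        pd, ph, pw = kd // 2, kh // 2, kw // 2
        dxp = np.zeros((b, d + 2 * pd, h + 2 * ph, w + 2 * pw, self.cin))
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    dxp[:, i:i + d, j:j + h, k:k + w, :] += dpatch[:, :, :, :, i, j, k, :]
        return dxp[:, pd:pd + d, ph:ph + h, pw:pw + w, :]


class BatchNorm:
    """Per-channel batch normalization over all leading axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * ivar
        out = self.gamma.value * xhat + self.beta.value
        return out, (xhat, ivar, axes, training)

    def backward(self, dout, cache):
        xhat, ivar, axes, training = cache
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value
        if not training:
            return dxhat * ivar
        n = np.prod([dout.shape[a] for a in axes])
        return (ivar / n) * (
            n * dxhat
            - dxhat.sum(axis=axes)
            - xhat * (dxhat * xhat).sum(axis=axes)
        )


class ReLU:
    def params(self):
        return []

    def forward(self, x, training=False):
        mask = x > 0
        return x * mask, mask

    def backward(self, dout, cache):
        return dout * cache


class Dense:
    def __init__(self, fin: int, fout: int, rng: np.random.Generator,
                 init_scale: float | None = None):
        scale = init_scale if init_scale is not None else np.sqrt(2.0 / fin)
        self.W = Param(rng.standard_normal((fin, fout)) * scale)
        self.b = Param(np.zeros(fout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        return x @ self.W.value + self.b.value, x

    def backward(self, dout, cache):
        self.W.grad += cache.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Dropout:
    """Inverted dropout; identity when not training or rate == 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate, self.rng = rate, rng

    def params(self):
        return []

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            return x, None
        mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * mask, mask

    def backward(self, dout, cache):
        return dout if cache is None else dout * cache


class GlobalAvgPool:
    """(B, N, H, W, C) -> (B, C)."""

    def params(self):
        return []

    def forward(self, x, training=False):
        return x.mean(axis=(1, 2, 3)), x.shape

    def backward(self, dout, cache):
        b, d, h, w, c = cache
        return np.broadcast_to(
            dout[:, None, None, None, :], cache
        ) / (d * h * w)


class SEAttention3D:
    """Squeeze-excitation channel attention over a (B, N, H, W, C) tensor.

    Squeeze: global average over the three feature/spatial axes.
    Excitation: C -> C/reduction (ReLU) -> C (sigmoid), both biased.
    Scale: per-channel multiply.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        if channels % reduction:
            raise ValueError(
                f"channels={channels} not divisible by reduction={reduction}"
            )
        hidden = channels // reduction
        self.fc1 = Dense(channels, hidden, rng)
        self.fc2 = Dense(hidden, channels, rng, init_scale=np.sqrt(1.0 / hidden))
        self.channels = channels

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def forward(self, x, training=False):
        s = x.mean(axis=(1, 2, 3))  # squeeze
        z1, c1 = self.fc1.forward(s)
        a1 = np.maximum(z1, 0.0)
        z2, c2 = self.fc2.forward(a1)
        e = sigmoid(z2)  # channel weights in (0, 1)
        out = x * e[:, None, None, None, :]
        return out, (x, c1, z1, c2, e)

    def backward(self, dout, cache):
        x, c1, z1, c2, e = cache
        dx = dout * cache[4][:, None, None, None, :]
        de = (dout * x).sum(axis=(1, 2, 3))
        dz2 = de * e * (1.0 - e)
        da1 = self.fc2.backward(dz2, c2)
        dz1 = da1 * (z1 > 0)
        ds = self.fc1.backward(dz1, c1)
        _, d, h, w, _ = x.shape
        dx += ds[:, None, None, None, :] / (d * h * w)
        return dx


class ConvLSTM3DCell:
    """Convolutional LSTM cell over a 3-D grid.

    Gate pre-activations are W_X * X_t + W_H * H_{t-1} + b (convolutions);
    optional per-channel peephole terms add w_c ⊙ C. Gate order in the fused
    convolution output is (i, f, g, o). The forget-gate bias starts at 1.
    """

    def __init__(self, cin: int, hidden: int, kernel: tuple[int, int, int],
                 rng: np.random.Generator, peephole: bool = False):
        self.cin, self.hidden, self.kernel = cin, hidden, tuple(kernel)
        k_prod = int(np.prod(kernel))
        self.conv_x = Conv3D(cin, 4 * hidden, kernel, rng, bias=True,
                             init_scale=np.sqrt(1.0 / (k_prod * cin)))
        self.conv_h = Conv3D(hidden, 4 * hidden, kernel, rng, bias=False,
                             init_scale=np.sqrt(1.0 / (k_prod * hidden)))
        self.conv_x.b.value[hidden:2 * hidden] = 1.0  # forget gate
        self.peephole = peephole
        if peephole:
            self.w_ci = Param(np.zeros(hidden))
            self.w_cf = Param(np.zeros(hidden))
            self.w_co = Param(np.zeros(hidden))

    def params(self):
        p = self.conv_x.params() + self.conv_h.params()
        if self.peephole:
            p += [self.w_ci, self.w_cf, self.w_co]
        return p

    def init_state(self, batch: int, grid: tuple[int, int, int]):
        shape = (batch, *grid, self.hidden)
        return np.zeros(shape), np.zeros(shape)

    def step(self, x, h_prev, c_prev, training=False):
        """One recurrence step; returns (h, c, gates, cache)."""
        if h_prev.shape != c_prev.shape or h_prev.shape[-1] != self.hidden:
            raise ValueError("state shape inconsistent with hidden channels")
        zx, cx = self.conv_x.forward(x, training)
        zh, ch = self.conv_h.forward(h_prev, training)
        z = zx + zh
        hd = self.hidden
        zi, zf, zg, zo = (z[..., :hd], z[..., hd:2 * hd],
                          z[..., 2 * hd:3 * hd], z[..., 3 * hd:])
        if self.peephole:
            zi = zi + self.w_ci.value * c_prev
            zf = zf + self.w_cf.value * c_prev
        i, f, g = sigmoid(zi), sigmoid(zf), np.tanh(zg)
        c = f * c_prev + i * g
        zo_eff = zo + self.w_co.value * c if self.peephole else zo
        o = sigmoid(zo_eff)
        tc = np.tanh(c)
        h = o * tc
        gates = {"i": i, "f": f, "g": g, "o": o}
        cache = (cx, ch, i, f, g, o, c_prev, c, tc)
        return h, c, gates, cache

    def step_backward(self, dh, dc, cache):
        """Backprop one step: returns (dx, dh_prev, dc_prev)."""
        cx, ch, i, f, g, o, c_prev, c, tc = cache
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        dzo = do * o * (1.0 - o)
        if self.peephole:
            self.w_co.grad += (dzo * c).sum(axis=tuple(range(c.ndim - 1)))
            dc = dc + dzo * self.w_co.value
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_prev = dc * f
        dzi = di * i * (1.0 - i)
        dzf = df * f * (1.0 - f)
        dzg = dg * (1.0 - g * g)
        if self.peephole:
            red = tuple(range(c.ndim - 1))
            self.w_ci.grad += (dzi * c_prev).sum(axis=red)
            self.w_cf.grad += (dzf * c_prev).sum(axis=red)
            dc_prev = dc_prev + dzi * self.w_ci.value + dzf * self.w_cf.value
        dz = np.concatenate([dzi, dzf, dzg, dzo], axis=-1)
        dx = self.conv_x.backward(dz, cx)
        dh_prev = self.conv_h.backward(dz, ch)
        return dx, dh_prev, dc_prev


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.beta1) * (p.grad - m)
            v += (1.0 - self.beta2) * (p.grad ** 2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
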