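"""Minimal tape-based reverse-mode automatic differentiation on numpy arrays.

The imputation networks are small (a few thousand parameters, sequence
length below ~20), so a lean scalar-graph engine over vectorized numpy
operations is fast enough for CPU training while keeping every run
bit-reproducible.  Recurrent cells (tanh RNN, LSTM) and the 1-D
convolution are fused nodes with hand-written backward passes so that an
epoch costs a few hundred numpy calls rather than tens of thousands.

Only the operations the generator/discriminator need are implemented.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special

__all__ = [
    "Tensor",
    "astensor",
    "add",
    "sub",
    "mul",
    "matmul",
    "exp",
    "log",
    "tanh",
    "sigmoid",
    "relu",
    "leaky_relu",
    "softplus",
    "absolute",
    "clamp",
    "tsum",
    "tmean",
    "concat",
    "reshape",
    "flip",
    "softmax",
    "conv1d_same",
    "conv1d_grouped",
    "maxpool1d",
    "rnn_tanh",
    "lstm",
    "dropout",
    "Adam",
]


DTYPE = np.float32  # network arithmetic; containers outside the engine stay float64


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # Operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, astensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, astensor(other))

    def __rsub__(self, other):
        return sub(astensor(other), self)

    def __mul__(self, other):
        return mul(self, astensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, astensor(-1.0))

    def __matmul__(self, other):
        return matmul(self, astensor(other))

    def __getitem__(self, key):
        return getitem(self, key)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward_fn) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward_fn
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad:
        t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


# Elementwise -----------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    def back(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))

    return _make(a.data + b.data, (a, b), back)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def back(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(-g, b.shape))

    return _make(a.data - b.data, (a, b), back)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def back(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), back)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def back(g):
        _accum(a, g * out_data)

    return _make(out_data, (a,), back)


def log(a: Tensor) -> Tensor:
    def back(g):
        _accum(a, g / a.data)

    return _make(np.log(a.data), (a,), back)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def back(g):
        _accum(a, g * (1.0 - out_data ** 2))

    return _make(out_data, (a,), back)


def sigmoid(a: Tensor) -> Tensor:
    out_data = _sigmoid(a.data)

    def back(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), back)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return special.expit(x)


def softplus(a: Tensor) -> Tensor:
    """log(1 + exp(x)), the numerically stable form of -log sigmoid(-x)."""
    out_data = np.logaddexp(0.0, a.data)
    sig = _sigmoid(a.data)

    def back(g):
        _accum(a, g * sig)

    return _make(out_data, (a,), back)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def back(g):
        _accum(a, g * mask)

    return _make(np.where(mask, a.data, 0.0), (a,), back)


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    mask = a.data > 0

    def back(g):
        _accum(a, g * np.where(mask, 1.0, slope))

    return _make(np.where(mask, a.data, slope * a.data), (a,), back)


def absolute(a: Tensor) -> Tensor:
    sign = np.sign(a.data)

    def back(g):
        _accum(a, g * sign)

    return _make(np.abs(a.data), (a,), back)


def clamp(a: Tensor, lo: float, hi: float) -> Tensor:
    inside = (a.data > lo) & (a.data < hi)

    def back(g):
        _accum(a, g * inside)

    return _make(np.clip(a.data, lo, hi), (a,), back)


# Shape / reductions ----------------------------------------------------


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def back(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.shape).copy())
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            _accum(a, np.broadcast_to(gg, a.shape).copy())

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), back)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]

    def back(g):
        if axis is None:
            _accum(a, np.broadcast_to(g / n, a.shape).copy())
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            _accum(a, np.broadcast_to(gg / n, a.shape).copy())

    return _make(a.data.mean(axis=axis, keepdims=keepdims), (a,), back)


def concat(tensors: list, axis: int = -1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accum(t, g[tuple(idx)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, back)


def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape

    def back(g):
        _accum(a, g.reshape(old))

    return _make(a.data.reshape(shape), (a,), back)


def flip(a: Tensor, axis: int) -> Tensor:
    def back(g):
        _accum(a, np.flip(g, axis=axis))

    return _make(np.flip(a.data, axis=axis), (a,), back)


def getitem(a: Tensor, key) -> Tensor:
    def back(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, key, g)
        _accum(a, ga)

    return _make(a.data[key], (a,), back)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """a @ b with ``b`` a 2-D weight matrix; ``a`` may have leading batch axes."""
    if b.data.ndim != 2:
        raise ValueError("matmul expects a 2-D right operand")

    def back(g):
        _accum(a, g @ b.data.T)
        p, n = b.data.shape
        _accum(b, a.data.reshape(-1, p).T @ g.reshape(-1, n))

    return _make(a.data @ b.data, (a, b), back)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    out_data = ez / ez.sum(axis=axis, keepdims=True)

    def back(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        _accum(a, out_data * (g - dot))

    return _make(out_data, (a,), back)


# Fused network layers --------------------------------------------------


def conv1d_same(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1-D convolution along axis 1 with 'same' zero padding, stride 1.

    x: (B, p, C_in); w: (k, C_in, C_out); b: (C_out,) -> (B, p, C_out).
    """
    k = w.data.shape[0]
    bsz, p, cin = x.data.shape
    cout = w.data.shape[2]
    left = (k - 1) // 2
    xp = np.zeros((bsz, p + k - 1, cin), dtype=DTYPE)
    xp[:, left:left + p, :] = x.data
    out_data = np.zeros((bsz, p, cout), dtype=DTYPE)
    for t in range(k):
        out_data += (xp[:, t:t + p, :].reshape(-1, cin) @ w.data[t]).reshape(bsz, p, cout)
    out_data += b.data

    def back(g):
        gxp = np.zeros_like(xp)
        gw = np.empty_like(w.data)
        g2 = g.reshape(-1, cout)
        for t in range(k):
            seg = xp[:, t:t + p, :].reshape(-1, cin)
            gw[t] = seg.T @ g2
            gxp[:, t:t + p, :] += (g2 @ w.data[t].T).reshape(bsz, p, cin)
        _accum(x, gxp[:, left:left + p, :])
        _accum(w, gw)
        _accum(b, g.sum(axis=(0, 1)))

    return _make(out_data, (x, w, b), back)


def conv1d_grouped(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Grouped 'same' 1-D convolution: independent weights per group.

    x: (G, B, p, C_in); w: (G, k, C_in, C_out); b: (G, 1, 1, C_out).
    Equivalent to running :func:`conv1d_same` separately per group but in
    a handful of broadcast matmuls.
    """
    gn, bsz, p, cin = x.data.shape
    k = w.data.shape[1]
    cout = w.data.shape[3]
    left = (k - 1) // 2
    xp = np.zeros((gn, bsz, p + k - 1, cin), dtype=DTYPE)
    xp[:, :, left:left + p, :] = x.data
    acc = np.zeros((gn, bsz * p, cout), dtype=DTYPE)
    for t in range(k):
        seg = np.ascontiguousarray(xp[:, :, t:t + p, :]).reshape(gn, bsz * p, cin)
        acc += seg @ w.data[:, t]
    out_data = acc.reshape(gn, bsz, p, cout) + b.data

    def back(g):
        gxp = np.zeros_like(xp)
        gw = np.empty_like(w.data)
        g2 = np.ascontiguousarray(g).reshape(gn, bsz * p, cout)
        for t in range(k):
            seg = np.ascontiguousarray(xp[:, :, t:t + p, :]).reshape(gn, bsz * p, cin)
            gw[:, t] = seg.transpose(0, 2, 1) @ g2
            gxp[:, :, t:t + p, :] += (g2 @ w.data[:, t].transpose(0, 2, 1)
                                      ).reshape(gn, bsz, p, cin)
        _accum(x, gxp[:, :, left:left + p, :])
        _accum(w, gw)
        _accum(b, g.sum(axis=(1, 2), keepdims=True))

    return _make(out_data, (x, w, b), back)


def maxpool1d(x: Tensor, size: int = 2) -> Tensor:
    """Max pooling along the second-to-last axis, ceil semantics.

    The last window may be short; ties send the gradient to the first
    maximal entry of the window.
    """
    *lead, p, c = x.data.shape
    pl = math.ceil(p / size)
    pad = pl * size - p
    if pad:
        xp = np.full((*lead, pl * size, c), -np.inf, dtype=DTYPE)
        xp[..., :p, :] = x.data
    else:
        xp = x.data
    if size == 2:
        a, bb = xp[..., 0::2, :], xp[..., 1::2, :]
        first = a >= bb
        out_data = np.where(first, a, bb)

        def back(g):
            gx = np.empty((*lead, pl * size, c), dtype=DTYPE)
            gx[..., 0::2, :] = np.where(first, g, 0.0)
            gx[..., 1::2, :] = np.where(first, 0.0, g)
            _accum(x, gx[..., :p, :])

        return _make(out_data, (x,), back)

    xr = xp.reshape(*lead, pl, size, c)
    arg = xr.argmax(axis=-2)
    out_data = np.take_along_axis(xr, arg[..., None, :], axis=-2)[..., 0, :]

    def back(g):
        gxr = np.zeros((*lead, pl, size, c), dtype=DTYPE)
        np.put_along_axis(gxr, arg[..., None, :], g[..., None, :], axis=-2)
        _accum(x, gxr.reshape(*lead, pl * size, c)[..., :p, :])

    return _make(out_data, (x,), back)


def rnn_tanh(x: Tensor, wx: Tensor, wh: Tensor, b: Tensor) -> Tensor:
    """One-layer tanh RNN over axis 1: h_i = tanh(x_i Wx + h_{i-1} Wh + b).

    x: (S, k, d) -> hidden states (S, k, h); h_0 = 0.
    """
    s, k, _ = x.data.shape
    h = wx.data.shape[1]
    hs = np.zeros((s, k, h), dtype=DTYPE)
    prev = np.zeros((s, h), dtype=DTYPE)
    for i in range(k):
        prev = np.tanh(x.data[:, i] @ wx.data + prev @ wh.data + b.data)
        hs[:, i] = prev

    def back(g):
        gx = np.zeros_like(x.data)
        gwx = np.zeros_like(wx.data)
        gwh = np.zeros_like(wh.data)
        gb = np.zeros_like(b.data)
        dh = np.zeros((s, h), dtype=DTYPE)
        for i in range(k - 1, -1, -1):
            da = (g[:, i] + dh) * (1.0 - hs[:, i] ** 2)
            gwx += x.data[:, i].T @ da
            gb += da.sum(axis=0)
            if i > 0:
                gwh += hs[:, i - 1].T @ da
            dh = da @ wh.data.T
            gx[:, i] = da @ wx.data.T
        _accum(x, gx)
        _accum(wx, gwx)
        _accum(wh, gwh)
        _accum(b, gb)

    return _make(hs, (x, wx, wh, b), back)


def lstm(x: Tensor, wx: Tensor, wh: Tensor, b: Tensor) -> Tensor:
    """One-layer LSTM over axis 1 returning all hidden states (S, k, u).

    Gate layout along the last axis of Wx/Wh/b is [input, forget, cell, output].
    """
    s, k, _ = x.data.shape
    u = wh.data.shape[0]
    hs = np.zeros((s, k, u), dtype=DTYPE)
    cache = []
    hprev = np.zeros((s, u), dtype=DTYPE)
    cprev = np.zeros((s, u), dtype=DTYPE)
    for t in range(k):
        z = x.data[:, t] @ wx.data + hprev @ wh.data + b.data
        i_g = _sigmoid(z[:, :u])
        f_g = _sigmoid(z[:, u:2 * u])
        g_g = np.tanh(z[:, 2 * u:3 * u])
        o_g = _sigmoid(z[:, 3 * u:])
        c = f_g * cprev + i_g * g_g
        tc = np.tanh(c)
        hnew = o_g * tc
        cache.append((i_g, f_g, g_g, o_g, cprev, tc, hprev))
        hprev, cprev = hnew, c
        hs[:, t] = hnew

    def back(g):
        gx = np.zeros_like(x.data)
        gwx = np.zeros_like(wx.data)
        gwh = np.zeros_like(wh.data)
        gb = np.zeros_like(b.data)
        dh = np.zeros((s, u), dtype=DTYPE)
        dc = np.zeros((s, u), dtype=DTYPE)
        for t in range(k - 1, -1, -1):
            i_g, f_g, g_g, o_g, cprev_t, tc, hprev_t = cache[t]
            dht = g[:, t] + dh
            do = dht * tc
            dct = dht * o_g * (1.0 - tc ** 2) + dc
            di = dct * g_g
            df = dct * cprev_t
            dg = dct * i_g
            dz = np.concatenate(
                [
                    di * i_g * (1.0 - i_g),
                    df * f_g * (1.0 - f_g),
                    dg * (1.0 - g_g ** 2),
                    do * o_g * (1.0 - o_g),
                ],
                axis=1,
            )
            gwx += x.data[:, t].T @ dz
            gwh += hprev_t.T @ dz
            gb += dz.sum(axis=0)
            gx[:, t] = dz @ wx.data.T
            dh = dz @ wh.data.T
            dc = dct * f_g
        _accum(x, gx)
        _accum(wx, gwx)
        _accum(wh, gwh)
        _accum(b, gb)

    return _make(hs, (x, wx, wh, b), back)


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate is 0."""
    if not training or rate == 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return mul(x, Tensor(mask))


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * g * g
            p.data -= self.lr * (self.m[i] / b1c) / (np.sqrt(self.v[i] / b2c) + self.eps)
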