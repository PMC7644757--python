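"""Minimal segmentation-network engine with explicit backpropagation.

Implements exactly the layer vocabulary the architecture grammar needs —
1-D same-padding convolution, (bi)LSTM, per-position dense layers and
dropout — plus softmax cross-entropy, RMSprop and proximal L1 shrinkage.
Everything operates on ``(channels, length)`` float64 arrays for a single
window; batching averages gradients across windows. Backward passes also
return the gradient with respect to the input, which the interpretation
pipeline relies on for input maximization.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv1d",
    "ReLU",
    "ChannelMaxPool",
    "LSTM",
    "Linear",
    "Dropout",
    "Sequential",
    "RMSprop",
    "softmax",
    "cross_entropy",
]


class Param:
    """A trainable tensor with gradient, optimizer cache and an L1 group."""

    __slots__ = ("value", "grad", "cache", "group")

    def __init__(self, value: np.ndarray, group: str = "other"):
        self.value = np.asarray(value, np.float64)
        self.grad = np.zeros_like(self.value)
        self.cache = np.zeros_like(self.value)
        self.group = group


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Stride-1 cross-correlation with same padding (kernel size odd)."""

    def __init__(self, in_channels, out_channels, kernel_size, rng, group="other"):
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        scale = np.sqrt(2.0 / (in_channels * kernel_size))
        self.W = Param(
            rng.normal(0.0, scale, (out_channels, in_channels, kernel_size)), group
        )
        self.b = Param(np.zeros(out_channels), group)

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        C, L = x.shape
        k = self.kernel_size
        pad = (k - 1) // 2
        xp = np.zeros((C, L + k - 1))
        xp[:, pad : pad + L] = x
        y = np.broadcast_to(self.b.value[:, None], (self.out_channels, L)).copy()
        W = self.W.value
        for d in range(k):
            y += W[:, :, d] @ xp[:, d : d + L]
        self._xp, self._L = xp, L
        return y

    def backward(self, dy):
        k = self.kernel_size
        pad = (k - 1) // 2
        L = self._L
        dxp = np.zeros_like(self._xp)
        for d in range(k):
            self.W.grad[:, :, d] += dy @ self._xp[:, d : d + L].T
            dxp[:, d : d + L] += self.W.value[:, :, d].T @ dy
        self.b.grad += dy.sum(axis=1)
        return dxp[:, pad : pad + L]


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class ChannelMaxPool(Layer):
    """Per-position max across channels (pooling over kernels, not length).

    Length pooling would break the per-nucleotide segmentation contract,
    so pooling, where requested, acts across the kernel axis only.
    """

    def forward(self, x, train=False, rng=None):
        self._arg = np.argmax(x, axis=0)
        self._shape = x.shape
        return x[self._arg, np.arange(x.shape[1])][None, :]

    def backward(self, dy):
        dx = np.zeros(self._shape)
        dx[self._arg, np.arange(self._shape[1])] = dy[0]
        return dx


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _LSTMDirection:
    """One direction of an LSTM over a (C, L) input; gates ordered i,f,g,o."""

    def __init__(self, in_channels, hidden_size, rng):
        H, C = hidden_size, in_channels
        s = 1.0 / np.sqrt(max(H, 1))
        self.Wx = Param(rng.uniform(-s, s, (4 * H, C)))
        self.Wh = Param(rng.uniform(-s, s, (4 * H, H)))
        self.b = Param(np.zeros(4 * H))
        self.H = H

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x):
        H = self.H
        C, L = x.shape
        self._x = x
        self._i = np.empty((H, L))
        self._f = np.empty((H, L))
        self._g = np.empty((H, L))
        self._o = np.empty((H, L))
        self._c = np.empty((H, L))
        self._tc = np.empty((H, L))
        self._h = np.empty((H, L))
        h = np.zeros(H)
        c = np.zeros(H)
        xa = self.Wx.value @ x + self.b.value[:, None]
        for t in range(L):
            a = xa[:, t] + self.Wh.value @ h
            i = _sigmoid(a[:H])
            f = _sigmoid(a[H : 2 * H])
            g = np.tanh(a[2 * H : 3 * H])
            o = _sigmoid(a[3 * H :])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            self._i[:, t] = i
            self._f[:, t] = f
            self._g[:, t] = g
            self._o[:, t] = o
            self._c[:, t] = c
            self._tc[:, t] = tc
            self._h[:, t] = h
        return self._h

    def backward(self, dH):
        H = self.H
        C, L = self._x.shape
        dA = np.empty((4 * H, L))
        dh_next = np.zeros(H)
        dc_next = np.zeros(H)
        for t in range(L - 1, -1, -1):
            i, f, g, o = self._i[:, t], self._f[:, t], self._g[:, t], self._o[:, t]
            tc = self._tc[:, t]
            c_prev = self._c[:, t - 1] if t > 0 else np.zeros(H)
            dh = dH[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate(
                (
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                )
            )
            dA[:, t] = da
            h_prev = self._h[:, t - 1] if t > 0 else np.zeros(H)
            self.Wh.grad += np.outer(da, h_prev)
            dh_next = self.Wh.value.T @ da
            dc_next = dc * f
        self.Wx.grad += dA @ self._x.T
        self.b.grad += dA.sum(axis=1)
        return self.Wx.value.T @ dA


class LSTM(Layer):
    """(Optionally bidirectional) LSTM; output is the per-position hidden state.

    Bidirectional runs a second cell over the reversed sequence and
    concatenates both hidden states position-wise.
    """

    def __init__(self, in_channels, hidden_size, rng, bidirectional=True):
        self.fwd = _LSTMDirection(in_channels, hidden_size, rng)
        self.bwd = _LSTMDirection(in_channels, hidden_size, rng) if bidirectional else None
        self.out_channels = hidden_size * (2 if bidirectional else 1)

    def params(self):
        ps = self.fwd.params()
        if self.bwd is not None:
            ps = ps + self.bwd.params()
        return ps

    def forward(self, x, train=False, rng=None):
        hf = self.fwd.forward(x)
        if self.bwd is None:
            return hf
        hb = self.bwd.forward(x[:, ::-1])
        return np.concatenate((hf, hb[:, ::-1]), axis=0)

    def backward(self, dy):
        H = self.fwd.H
        dx = self.fwd.backward(dy[:H])
        if self.bwd is not None:
            dx = dx + self.bwd.backward(dy[H:, ::-1])[:, ::-1]
        return dx


class Linear(Layer):
    """Per-position affine map (equivalent to a kernel-1 convolution)."""

    def __init__(self, in_channels, out_channels, rng, group="other"):
        scale = np.sqrt(2.0 / in_channels)
        self.W = Param(rng.normal(0.0, scale, (out_channels, in_channels)), group)
        self.b = Param(np.zeros(out_channels), group)

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return self.W.value @ x + self.b.value[:, None]

    def backward(self, dy):
        self.W.grad += dy @ self._x.T
        self.b.grad += dy.sum(axis=1)
        return self.W.value.T @ dy


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p=0.5):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state, strict=True):
            p.value[...] = v


class RMSprop:
    """RMSprop with optional per-group L1 regularization.

    The L1 term enters the loss gradient (lambda * sign(w)), so under
    RMSprop's gradient normalization an unnecessary weight — one whose
    data gradient the penalty dominates — decays at the full learning
    rate. A preconditioned proximal shrink (lr * lambda / sqrt(cache))
    then snaps such weights to exact zeros, which the feature-importance
    analysis relies on: exactly-zero first-layer weights mark features
    the model ignores.
    """

    def __init__(self, params, lr=1e-3, rho=0.9, eps=1e-8, l1=None):
        self.params = list(params)
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.l1 = dict(l1 or {})

    def step(self):
        for p in self.params:
            lam = self.l1.get(p.group, 0.0)
            grad = p.grad
            if lam > 0.0:
                grad = grad + lam * np.sign(p.value)
            p.cache[...] = self.rho * p.cache + (1.0 - self.rho) * grad**2
            denom = np.sqrt(p.cache) + self.eps
            p.value -= self.lr * grad / denom
            if lam > 0.0:
                p.value[...] = np.sign(p.value) * np.maximum(
                    np.abs(p.value) - self.lr * lam / denom, 0.0
                )

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0


def softmax(logits: np.ndarray) -> np.ndarray:
    """Column-wise softmax of a (n_classes, L) logit matrix."""
    m = logits.max(axis=0, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=0, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean per-position two-class cross entropy; returns (loss, dlogits)."""
    L = logits.shape[1]
    p = softmax(logits)
    idx = np.arange(L)
    labels = labels.astype(np.int64)
    loss = float(-np.log(np.maximum(p[labels, idx], 1e-300)).mean())
    dlogits = p.copy()
    dlogits[labels, idx] -= 1.0
    dlogits /= L
    return loss, dlogits
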