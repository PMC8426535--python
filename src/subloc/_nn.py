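"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This backend exists so the sequence model (bidirectional LSTM, multi-head
self-attention, dense head) can be trained on a plain CPU scientific stack.
It implements exactly the operations the model needs: affine maps, batched
matrix products, element-wise nonlinearities, a masked softmax, max-pooling,
reductions, dropout, and a fused bidirectional-LSTM layer whose backward pass
is hand-derived backpropagation-through-time. Gradients are verified against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


class Tensor:
    """A node in the computation graph: a value, a gradient, and a backward rule."""

    __slots__ = ("value", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, value, parents=(), backward=None, requires_grad=False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- graph mechanics ---------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.value)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        if not self.requires_grad and self._backward is None:
            return
        self.grad = grad if self.grad is None else self.grad + grad

    @property
    def shape(self):
        return self.value.shape

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.value + other.value, (self, other))
        out._backward = lambda g: (
            self._accum(_unbroadcast(g, self.value.shape)),
            other._accum(_unbroadcast(g, other.value.shape)),
        )
        return out

    __radd__ = __add__

    def __sub__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.value - other.value, (self, other))
        out._backward = lambda g: (
            self._accum(_unbroadcast(g, self.value.shape)),
            other._accum(_unbroadcast(-g, other.value.shape)),
        )
        return out

    def __rsub__(self, other):
        return _as_tensor(other).__sub__(self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.value * other.value, (self, other))
        out._backward = lambda g: (
            self._accum(_unbroadcast(g * other.value, self.value.shape)),
            other._accum(_unbroadcast(g * self.value, other.value.shape)),
        )
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    # -- shaping -----------------------------------------------------------

    def reshape(self, *shape):
        old = self.value.shape
        out = Tensor(self.value.reshape(*shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(old))
        return out

    # -- nonlinearities ----------------------------------------------------

    def tanh(self):
        y = np.tanh(self.value)
        out = Tensor(y, (self,))
        out._backward = lambda g: self._accum(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = _sigmoid(self.value)
        out = Tensor(y, (self,))
        out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def log(self, eps=1e-12):
        x = self.value + eps
        out = Tensor(np.log(x), (self,))
        out._backward = lambda g: self._accum(g / x)
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.value.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis):
        """Maximum along an axis; gradient routes to the first arg-max."""
        idx = np.argmax(self.value, axis=axis)
        out_val = np.max(self.value, axis=axis)
        out = Tensor(out_val, (self,))

        def bw(g):
            grad = np.zeros_like(self.value)
            np.put_along_axis(
                grad, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis
            )
            self._accum(grad)

        out._backward = bw
        return out

    # -- linear algebra ----------------------------------------------------

    def linear(self, W: "Tensor", b: "Tensor" = None):
        """x @ W (+ b) with x of shape (..., D) and W of shape (D, K)."""
        y = self.value @ W.value
        if b is not None:
            y = y + b.value
        parents = (self, W) if b is None else (self, W, b)
        out = Tensor(y, parents)

        def bw(g):
            self._accum(g @ W.value.T)
            g2 = g.reshape(-1, g.shape[-1])
            x2 = self.value.reshape(-1, self.value.shape[-1])
            W._accum(x2.T @ g2)
            if b is not None:
                b._accum(g2.sum(axis=0))

        out._backward = bw
        return out

    def bmm(self, other: "Tensor"):
        """Batched matrix product: (B, m, k) @ (B, k, n)."""
        out = Tensor(self.value @ other.value, (self, other))
        out._backward = lambda g: (
            self._accum(g @ np.swapaxes(other.value, -1, -2)),
            other._accum(np.swapaxes(self.value, -1, -2) @ g),
        )
        return out

    def swap(self):
        """Transpose the last two axes."""
        out = Tensor(np.swapaxes(self.value, -1, -2), (self,))
        out._backward = lambda g: self._accum(np.swapaxes(g, -1, -2))
        return out

    # -- model-specific ops ------------------------------------------------

    def masked_softmax(self, mask: np.ndarray):
        """Softmax over the last axis restricted to mask==1 positions.

        Masked positions get exactly zero weight. Raises if a row has no
        valid position at all.
        """
        m = np.broadcast_to(mask.astype(bool), self.value.shape)
        if not m.any(axis=-1).all():
            raise ValueError("softmax over an all-masked axis")
        x = np.where(m, self.value, -np.inf)
        x = x - x.max(axis=-1, keepdims=True)
        e = np.exp(x)
        e = np.where(m, e, 0.0)
        y = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(y, (self,))

        def bw(g):
            dot = (g * y).sum(axis=-1, keepdims=True)
            self._accum(y * (g - dot))

        out._backward = bw
        return out

    def dropout(self, rate: float, rng: np.random.Generator):
        """Inverted dropout; identity when rate == 0."""
        if rate <= 0.0:
            return self
        keep = (rng.random(self.value.shape) >= rate) / (1.0 - rate)
        out = Tensor(self.value * keep, (self,))
        out._backward = lambda g: self._accum(g * keep)
        return out

    def concat_last(self, other: "Tensor"):
        k = self.value.shape[-1]
        out = Tensor(np.concatenate([self.value, other.value], axis=-1), (self, other))
        out._backward = lambda g: (
            self._accum(g[..., :k]),
            other._accum(g[..., k:]),
        )
        return out

    def flip_time(self):
        """Reverse axis 1 (the sequence axis of a (B, L, D) tensor)."""
        out = Tensor(self.value[:, ::-1], (self,))
        out._backward = lambda g: self._accum(g[:, ::-1])
        return out

    def lstm(self, Wx: "Tensor", Wh: "Tensor", b: "Tensor", mask: np.ndarray):
        """One unidirectional LSTM layer over a (B, L, D) input.

        `mask` is (B, L) with 1 for valid positions. State is carried
        through masked steps unchanged and the emitted output is zeroed
        there, so left- or right-padding both work. Gate layout in the
        4u-wide weights is [input, forget, cell, output].
        """
        x, mWx, mWh, mb = self.value, Wx.value, Wh.value, b.value
        B, L, D = x.shape
        u = mWh.shape[0]
        mk = mask.astype(np.float64)
        xW = x @ mWx  # (B, L, 4u)

        H = np.zeros((B, L, u))
        cache = []
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        for t in range(L):
            z = xW[:, t] + h @ mWh + mb
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            m = mk[:, t : t + 1]
            cache.append((i, f, g, o, c, tc, h, m))
            h = m * h_new + (1.0 - m) * h
            c = m * c_new + (1.0 - m) * c
            H[:, t] = m * h_new

        out = Tensor(H, (self, Wx, Wh, b))

        def bw(dH):
            dx = np.zeros_like(x)
            dWx = np.zeros_like(mWx)
            dWh = np.zeros_like(mWh)
            db = np.zeros_like(mb)
            gh = np.zeros((B, u))  # grad wrt carried h
            gc = np.zeros((B, u))
            for t in range(L - 1, -1, -1):
                i, f, g, o, c_prev, tc, h_prev, m = cache[t]
                dh_new = m * (gh + dH[:, t])
                dc_new = m * gc + dh_new * o * (1.0 - tc * tc)
                do = dh_new * tc
                df = dc_new * c_prev
                di = dc_new * g
                dg = dc_new * i
                dz = np.concatenate(
                    [
                        di * i * (1.0 - i),
                        df * f * (1.0 - f),
                        dg * (1.0 - g * g),
                        do * o * (1.0 - o),
                    ],
                    axis=1,
                )
                dx[:, t] = dz @ mWx.T
                dWx += x[:, t].T @ dz
                dWh += h_prev.T @ dz
                db += dz.sum(axis=0)
                gh = (1.0 - m) * gh + dz @ mWh.T
                gc = (1.0 - m) * gc + dc_new * f
            self._accum(dx)
            Wx._accum(dWx)
            Wh._accum(dWh)
            b._accum(db)

        out._backward = bw
        return out


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum a broadcast gradient back down to `shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
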