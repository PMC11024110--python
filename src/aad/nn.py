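"""Minimal reverse-mode automatic differentiation and the recurrent nets.

A small tape-based autodiff over numpy arrays, sized for the models this
package trains: stacked LSTM / bidirectional LSTM sequence classifiers and
the GRU + 1-D-convolution Q-network of the attention-decoding agent.
Gradients are exact (verified against finite differences in the test
suite); optimization is Adam.  Everything is seeded and deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Linear", "GRUCell", "LSTMCell", "Conv1dSingleChannel",
           "Adam", "softmax_cross_entropy", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "_parents", "_backward")
    __array_priority__ = 100  # keep numpy from hijacking binary ops

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph mechanics ---------------------------------------------------
    def backward(self) -> None:
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- ops ---------------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g)
            other._accum(g)

        return Tensor(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor(self.data @ other.data, (self, other), bw)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * out * (1 - out))

        return Tensor(out, (self,), bw)

    def tanh(self):
        out = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1 - out ** 2))

        return Tensor(out, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor(self.data * mask, (self,), bw)

    def square(self):
        def bw(g):
            self._accum(2 * g * self.data)

        return Tensor(self.data ** 2, (self,), bw)

    def sum(self):
        def bw(g):
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor(self.data.sum(), (self,), bw)

    def mean(self):
        n = self.data.size

        def bw(g):
            self._accum(np.broadcast_to(g / n, self.data.shape).copy())

        return Tensor(self.data.mean(), (self,), bw)

    def mean_last(self):
        """Mean over the last axis."""
        n = self.data.shape[-1]

        def bw(g):
            self._accum(np.repeat(np.expand_dims(g / n, -1), n, axis=-1))

        return Tensor(self.data.mean(axis=-1), (self,), bw)

    def maximum(self, other: "Tensor"):
        other = self._wrap(other)
        take_self = self.data >= other.data

        def bw(g):
            self._accum(g * take_self)
            other._accum(g * ~take_self)

        return Tensor(np.where(take_self, self.data, other.data),
                      (self, other), bw)

    def concat(self, other: "Tensor"):
        """Concatenate along the last axis."""
        other = self._wrap(other)
        n = self.data.shape[-1]

        def bw(g):
            self._accum(g[..., :n])
            other._accum(g[..., n:])

        return Tensor(np.concatenate([self.data, other.data], axis=-1),
                      (self, other), bw)

    def gather_cols(self, idx: np.ndarray):
        """Pick one column per row of a 2-D tensor: out[i] = self[i, idx[i]]."""
        rows = np.arange(self.data.shape[0])

        def bw(g):
            full = np.zeros_like(self.data)
            full[rows, idx] = g
            self._accum(full)

        return Tensor(self.data[rows, idx], (self,), bw)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer class targets; fused stable backward."""
    p = softmax(logits.data)
    n = logits.data.shape[0]
    nll = -np.log(np.clip(p[np.arange(n), targets], 1e-12, None)).mean()

    def bw(g):
        grad = p.copy()
        grad[np.arange(n), targets] -= 1.0
        logits._accum(g * grad / n)

    return Tensor(nll, (logits,), bw)


# ---------------------------------------------------------------------------
# layers

def _glorot(rng: np.random.Generator, nin: int, nout: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (nin + nout))
    return rng.uniform(-lim, lim, size=(nin, nout))


class Linear:
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        self.W = Tensor(_glorot(rng, nin, nout))
        self.b = Tensor(np.zeros(nout))

    @property
    def params(self):
        return [self.W, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class GRUCell:
    """Gated recurrent unit: h' = (1-z)*n + z*h (update gate keeps history)."""

    def __init__(self, nin: int, nh: int, rng: np.random.Generator):
        self.nh = nh
        self.Wz = Tensor(_glorot(rng, nin, nh)); self.Uz = Tensor(_glorot(rng, nh, nh))
        self.Wr = Tensor(_glorot(rng, nin, nh)); self.Ur = Tensor(_glorot(rng, nh, nh))
        self.Wn = Tensor(_glorot(rng, nin, nh)); self.Un = Tensor(_glorot(rng, nh, nh))
        self.bz = Tensor(np.zeros(nh)); self.br = Tensor(np.zeros(nh))
        self.bn = Tensor(np.zeros(nh))

    @property
    def params(self):
        return [self.Wz, self.Uz, self.Wr, self.Ur, self.Wn, self.Un,
                self.bz, self.br, self.bn]

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        z = (x @ self.Wz + h @ self.Uz + self.bz).sigmoid()
        r = (x @ self.Wr + h @ self.Ur + self.br).sigmoid()
        n = (x @ self.Wn + r * (h @ self.Un) + self.bn).tanh()
        one = Tensor(np.ones_like(z.data))
        return (one - z) * n + z * h


class LSTMCell:
    def __init__(self, nin: int, nh: int, rng: np.random.Generator):
        self.nh = nh
        self.W = Tensor(_glorot(rng, nin, 4 * nh))
        self.U = Tensor(_glorot(rng, nh, 4 * nh))
        b = np.zeros(4 * nh)
        b[nh:2 * nh] = 1.0  # forget-gate bias 1: standard stabilizer
        self.b = Tensor(b)

    @property
    def params(self):
        return [self.W, self.U, self.b]

    def __call__(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        nh = self.nh
        gates = x @ self.W + h @ self.U + self.b
        i = _slice_cols(gates, 0, nh).sigmoid()
        f = _slice_cols(gates, nh, 2 * nh).sigmoid()
        o = _slice_cols(gates, 2 * nh, 3 * nh).sigmoid()
        cand = _slice_cols(gates, 3 * nh, 4 * nh).tanh()
        c_new = f * c + i * cand
        h_new = o * c_new.tanh()
        return h_new, c_new


def _slice_cols(t: Tensor, a: int, b: int) -> Tensor:
    def bw(g):
        full = np.zeros_like(t.data)
        full[..., a:b] = g
        t._accum(full)

    return Tensor(t.data[..., a:b], (t,), bw)


class Conv1dSingleChannel:
    """1-D convolution of a (batch, width) signal: (batch, filters, width-k+1)."""

    def __init__(self, n_filters: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.W = Tensor(_glorot(rng, kernel, n_filters).T)  # (filters, kernel)
        self.b = Tensor(np.zeros(n_filters))

    @property
    def params(self):
        return [self.W, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        k = self.kernel
        wo = x.data.shape[1] - k + 1
        if wo < 1:
            raise ValueError("input narrower than the convolution kernel")
        windows = np.lib.stride_tricks.sliding_window_view(x.data, k, axis=1)
        out = np.einsum("bwk,fk->bfw", windows, self.W.data)
        out += self.b.data[None, :, None]
        W, b = self.W, self.b

        def bw(g):
            W._accum(np.einsum("bfw,bwk->fk", g, windows))
            dx = np.zeros_like(x.data)
            gw = np.einsum("bfw,fk->bwk", g, W.data)
            for j in range(k):
                dx[:, j:j + wo] += gw[:, :, j]
            x._accum(dx)
            b._accum(g.sum(axis=(0, 2)))

        return Tensor(out, (x, W, b), bw)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
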