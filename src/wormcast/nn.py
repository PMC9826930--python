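"""Minimal reverse-mode automatic differentiation and neural-net layers.

A small tape-based autodiff engine on numpy arrays, providing exactly the
operations the lifespan forecaster needs: broadcast arithmetic, matmul,
sigmoid/tanh/relu, slicing and concatenation, reductions, and a strided 2-D
convolution via im2col. Layers (Linear, Conv2d, LSTMCell) and a plain-SGD
optimizer (optional momentum) sit on top.

Gradients are checked against central finite differences in the test suite;
everything is deterministic given the numpy Generator used for init.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "scatter_rows",
    "Linear",
    "Conv2d",
    "LSTMCell",
    "Module",
    "SGD",
    "set_default_dtype",
    "get_default_dtype",
]

# float32 keeps memory traffic (the bottleneck of the conv path) low;
# gradient-check tests switch to float64 for finite-difference accuracy.
_DEFAULT_DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype).type


def get_default_dtype():
    return _DEFAULT_DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (long sequences)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = (np.ones_like(self.data) if grad is None
                     else np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, self._coerce(other)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)

        return Tensor._make(a.data @ b.data, (a, b), backward)

    __matmul__ = matmul

    # -- nonlinearities -----------------------------------------------------

    def sigmoid(self) -> "Tensor":
        x = self.data
        out_data = np.empty_like(x)
        pos = x >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out_data[~pos] = ex / (1.0 + ex)
        a = self

        def backward(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)
        a = self

        def backward(g):
            a._accumulate(g * (1.0 - out_data * out_data))

        return Tensor._make(out_data, (a,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0
        a = self

        def backward(g):
            a._accumulate(g * mask)

        return Tensor._make(self.data * mask, (a,), backward)

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        a = self
        old = self.data.shape

        def backward(g):
            a._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (a,), backward)

    def __getitem__(self, idx) -> "Tensor":
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            full[idx] = g
            a._accumulate(full)

        return Tensor._make(self.data[idx], (a,), backward)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def backward(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy())
                return
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            if not keepdims:
                for ax in sorted(ax % a.data.ndim for ax in axes):
                    g = np.expand_dims(g, ax)
            a._accumulate(np.broadcast_to(g, a.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)
    parents = tuple(tensors)

    def backward(g):
        for t, lo, hi in zip(parents, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(np.concatenate(datas, axis=axis), parents, backward)


def scatter_rows(src: Tensor, index: np.ndarray, n_rows: int) -> Tensor:
    """Place rows of ``src`` at ``index`` in a zero matrix of ``n_rows`` rows.

    Lets expensive per-frame encoders run on valid frames only, with the
    results scattered back into the padded (rows = batch*time) layout.
    """
    out = np.zeros((n_rows,) + src.data.shape[1:], dtype=src.data.dtype)
    out[index] = src.data

    def backward(g):
        src._accumulate(g[index])

    return Tensor._make(out, (src,), backward)


# -- convolution (im2col) ---------------------------------------------------


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, ho, wo, k, k),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
    )
    return view.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k), ho, wo


def _col2im(dcol: np.ndarray, xshape, k: int, stride: int, pad: int, ho: int, wo: int) -> np.ndarray:
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcol.dtype)
    d6 = dcol.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d6[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 2, pad: int = 1) -> Tensor:
    """2-D convolution; x (N,C,H,W), weight (O,C,k,k), bias (O,)."""
    o, c, k, _ = weight.shape
    col, ho, wo = _im2col(x.data, k, stride, pad)
    wmat = weight.data.reshape(o, c * k * k)
    out = (col @ wmat.T + bias.data).reshape(x.data.shape[0], ho, wo, o).transpose(0, 3, 1, 2)

    def backward(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(-1, o)
        if weight.requires_grad:
            weight._accumulate((g2.T @ col).reshape(weight.shape))
        if bias.requires_grad:
            bias._accumulate(g2.sum(axis=0))
        if x.requires_grad:
            dcol = g2 @ wmat
            x._accumulate(_col2im(dcol, x.data.shape, k, stride, pad, ho, wo))

    return Tensor._make(out, (x, weight, bias), backward)


# -- layers ------------------------------------------------------------------


class Module:
    """Parameter container with recursive collection."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state does not match parameter count")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError("state shape mismatch")
            p.data = s.copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Tensor(_glorot(rng, n_in, n_out, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 2, pad: int = 1):
        fan_in, fan_out = c_in * k * k, c_out * k * k
        self.weight = Tensor(_glorot(rng, fan_in, fan_out, (c_out, c_in, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.pad = pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class LSTMCell(Module):
    """Standard LSTM cell; forget-gate bias initialized to 1."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.weight = Tensor(
            _glorot(rng, n_in + n_hidden, 4 * n_hidden, (n_in + n_hidden, 4 * n_hidden)),
            requires_grad=True,
        )
        bias = np.zeros(4 * n_hidden)
        bias[n_hidden : 2 * n_hidden] = 1.0
        self.bias = Tensor(bias, requires_grad=True)

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        nh = self.n_hidden
        z = concat([x, h], axis=1) @ self.weight + self.bias
        i = z[:, :nh].sigmoid()
        f = z[:, nh : 2 * nh].sigmoid()
        g = z[:, 2 * nh : 3 * nh].tanh()
        o = z[:, 3 * nh :].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new

    def run(self, xs: list[Tensor], mask: np.ndarray) -> Tensor:
        """Run over a padded sequence; mask (B, T) marks valid steps.

        Masked steps leave the state untouched, so front padding contributes
        nothing; returns the final hidden state (B, n_hidden).
        """
        batch = xs[0].shape[0]
        h = Tensor(np.zeros((batch, self.n_hidden)))
        c = Tensor(np.zeros((batch, self.n_hidden)))
        for t, x in enumerate(xs):
            m = mask[:, t : t + 1]
            if not m.any():
                continue
            h_new, c_new = self.step(x, h, c)
            h = h_new * m + h * (1.0 - m)
            c = c_new * m + c * (1.0 - m)
        return h


class SGD:
    """Stochastic gradient descent, optionally with classical momentum."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            if self.momentum > 0.0:
                v *= self.momentum
                v += p.grad
                p.data -= self.lr * v
            else:
                p.data -= self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
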