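"""Minimal reverse-mode automatic differentiation on numpy arrays.

The models in this package are small (a few hundred nodes, d ~ 64) and must
train on one CPU with no deep-learning framework available, so we carry a
compact tape-based autodiff engine instead of depending on one.  Only the
operations the pipeline needs are implemented: broadcast arithmetic, (batched)
matmul, sparse-constant matmul, gather, stack, softmax, tanh, leaky-relu,
layer norm and a numerically stable binary cross-entropy with logits.

All arrays are float64; gradients accumulate by summation, and broadcasting
in the forward pass is undone by summing over the broadcast axes in the
backward pass.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "matmul",
    "spmm",
    "gather",
    "stack",
    "concat",
    "tanh",
    "leaky_relu",
    "sigmoid",
    "softmax",
    "layer_norm",
    "bce_with_logits",
    "Adam",
    "glorot",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff graph wrapping an ``np.ndarray``."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        name: str = "",
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = f" name={self.name!r}" if self.name else ""
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad}{tag})"

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("tensor/tensor division is not supported")
        return mul(self, 1.0 / float(other))

    # -- autodiff -------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode accumulation from this tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack_.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in ts)


def _make(data, parents, backward) -> Tensor:
    if _needs(*parents):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data - b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(-g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def matmul(a, b) -> Tensor:
    """Matrix product supporting leading batch dimensions (np.matmul rules)."""
    a, b = as_tensor(a), as_tensor(b)
    if a.ndim < 2 or b.ndim < 2:
        raise ValueError("matmul requires >=2-D operands")
    out_data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accumulate(_unbroadcast(ga, a.data.shape))
        b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), backward)


def spmm(mat: sp.spmatrix, x) -> Tensor:
    """Multiply a constant scipy sparse matrix by a dense tensor."""
    x = as_tensor(x)
    mat = sp.csr_matrix(mat)
    out_data = mat @ x.data

    def backward(g):
        x._accumulate(mat.T @ g)

    return _make(out_data, (x,), backward)


def gather(x, index) -> Tensor:
    """Select rows ``x[index]`` along axis 0."""
    x = as_tensor(x)
    index = np.asarray(index, dtype=np.intp)
    out_data = x.data[index]

    def backward(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, index, g)
        x._accumulate(gx)

    return _make(out_data, (x,), backward)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in ts], axis=axis)

    def backward(g):
        pieces = np.split(g, len(ts), axis=axis)
        for t, piece in zip(ts, pieces):
            t._accumulate(np.squeeze(piece, axis=axis))

    return _make(out_data, tuple(ts), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return _make(out_data, tuple(ts), backward)


def transpose(x, axes=None) -> Tensor:
    x = as_tensor(x)
    if axes is None:
        axes = tuple(reversed(range(x.ndim)))
    out_data = np.transpose(x.data, axes)
    inv = np.argsort(axes)

    def backward(g):
        x._accumulate(np.transpose(g, inv))

    return _make(out_data, (x,), backward)


def reshape(x, shape) -> Tensor:
    x = as_tensor(x)
    out_data = x.data.reshape(shape)
    orig = x.data.shape

    def backward(g):
        x._accumulate(g.reshape(orig))

    return _make(out_data, (x,), backward)


def sum_(x, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g, x.data.shape).copy())

    return _make(out_data, (x,), backward)


def mean(x, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    n = x.data.size if axis is None else x.data.shape[axis]
    return mul(sum_(x, axis=axis, keepdims=keepdims), 1.0 / n)


def tanh(x) -> Tensor:
    x = as_tensor(x)
    out_data = np.tanh(x.data)

    def backward(g):
        x._accumulate(g * (1.0 - out_data**2))

    return _make(out_data, (x,), backward)


def leaky_relu(x, slope: float = 0.01) -> Tensor:
    x = as_tensor(x)
    out_data = np.where(x.data >= 0, x.data, slope * x.data)

    def backward(g):
        x._accumulate(g * np.where(x.data >= 0, 1.0, slope))

    return _make(out_data, (x,), backward)


def sigmoid(x) -> Tensor:
    x = as_tensor(x)
    out_data = np.empty_like(x.data)
    pos = x.data >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    ex = np.exp(x.data[~pos])
    out_data[~pos] = ex / (1.0 + ex)

    def backward(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (x,), backward)


def softmax(x, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        x._accumulate(out_data * (g - dot))

    return _make(out_data, (x,), backward)


def layer_norm(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * gamma.data + beta.data
    d = x.data.shape[-1]

    def backward(g):
        gg = g * gamma.data
        gx = inv * (
            gg
            - gg.mean(axis=-1, keepdims=True)
            - xhat * (gg * xhat).mean(axis=-1, keepdims=True)
        )
        x._accumulate(gx)
        reduce_axes = tuple(range(g.ndim - 1))
        gamma._accumulate(_unbroadcast((g * xhat).sum(axis=reduce_axes), gamma.data.shape))
        beta._accumulate(_unbroadcast(g.sum(axis=reduce_axes), beta.data.shape))

    _ = d
    return _make(out_data, (x, gamma, beta), backward)


def bce_with_logits(logits, labels) -> Tensor:
    """Mean binary cross-entropy; ``labels`` is a constant 0/1 array."""
    logits = as_tensor(logits)
    y = np.asarray(labels, dtype=np.float64)
    z = logits.data
    # softplus(z) - y*z computed stably
    loss = np.maximum(z, 0) - y * z + np.log1p(np.exp(-np.abs(z)))
    out_data = np.array(loss.mean())
    n = z.size

    def backward(g):
        p = np.empty_like(z)
        pos = z >= 0
        p[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        p[~pos] = ez / (1.0 + ez)
        logits._accumulate(g * (p - y) / n)

    return _make(out_data, (logits,), backward)


# ---------------------------------------------------------------------------
# parameters and optimizer
# ---------------------------------------------------------------------------

def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> Tensor:
    """Glorot-uniform initialized parameter tensor."""
    fan_in = shape[-1] if len(shape) > 1 else shape[0]
    fan_out = shape[0] if len(shape) > 1 else shape[0]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Adam:
    """Adam with (coupled) L2 weight decay."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": self._m, "v": self._v}
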