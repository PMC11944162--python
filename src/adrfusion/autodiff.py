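"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Float64 throughout; the package favours numerical transparency over speed,
which keeps the layer oracles (dense brute-force re-implementations in the
test suite) meaningful at tight tolerances.

The public surface is the :class:`Tensor` class plus a handful of free
functions (``concat``, ``stack``, ``segment_sum`` ...).  Only the operations
the model needs are implemented; each op registers a closure that scatters
the upstream gradient into its inputs.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_children")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _children: tuple["Tensor", ...] = (),
        _backward: Callable[[Array], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: Array | None = None
        self._children = _children
        self._backward = _backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: Array) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- graph construction helper -------------------------------------------
    @staticmethod
    def _make(data: Array, children: Sequence["Tensor"], backward) -> "Tensor":
        req = any(c.requires_grad for c in children)
        return Tensor(
            data,
            requires_grad=req,
            _children=tuple(children) if req else (),
            _backward=backward if req else None,
        )

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g: Array) -> None:
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g / other.data)
            if other.requires_grad:
                other._accumulate(-g * self.data / (other.data**2))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g: Array) -> None:
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accumulate(np.swapaxes(self.data, -1, -2) @ g)

        return Tensor._make(out_data, (self, other), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        out_data = self.data.reshape(*shape)

        def backward(g: Array) -> None:
            self._accumulate(g.reshape(orig))

        return Tensor._make(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)

        def backward(g: Array) -> None:
            self._accumulate(np.swapaxes(g, a, b))

        return Tensor._make(out_data, (self,), backward)

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g: Array) -> None:
            buf = np.zeros_like(self.data)
            np.add.at(buf, idx, g)
            self._accumulate(buf)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: Array) -> None:
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient flows to the first arg-max entry."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        idx = np.argmax(self.data, axis=axis)

        def backward(g: Array) -> None:
            g = np.asarray(g)
            if keepdims:
                g = np.squeeze(g, axis=axis)
            buf = np.zeros_like(self.data)
            np.put_along_axis(
                buf, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis
            )
            self._accumulate(buf)

        return Tensor._make(out_data, (self,), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def backward(g: Array) -> None:
            self._accumulate(g * mask)

        return Tensor._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out_data = np.where(mask, self.data, slope * self.data)

        def backward(g: Array) -> None:
            self._accumulate(g * np.where(mask, 1.0, slope))

        return Tensor._make(out_data, (self,), backward)

    def elu(self, alpha: float = 1.0):
        mask = self.data > 0
        expm = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out_data = np.where(mask, self.data, expm)

        def backward(g: Array) -> None:
            self._accumulate(g * np.where(mask, 1.0, expm + alpha))

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g: Array) -> None:
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g: Array) -> None:
            self._accumulate(g / self.data)

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g: Array) -> None:
            self._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g: Array) -> None:
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def softplus(self):
        """log(1 + e^x), computed stably; derivative is sigmoid(x)."""
        out_data = np.logaddexp(0.0, self.data)

        def backward(g: Array) -> None:
            self._accumulate(g / (1.0 + np.exp(-self.data)))

        return Tensor._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1, mask: Array | None = None):
        """Softmax along ``axis``; positions where ``mask`` is False get
        weight exactly 0 and receive no gradient."""
        x = self.data
        if mask is not None:
            x = np.where(mask, x, -np.inf)
        shifted = x - np.max(x, axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)
        if mask is not None:
            out_data = np.where(mask, out_data, 0.0)

        def backward(g: Array) -> None:
            inner = (g * out_data).sum(axis=axis, keepdims=True)
            self._accumulate(out_data * (g - inner))

        return Tensor._make(out_data, (self,), backward)

    # -- backprop ------------------------------------------------------------
    def backward(self, grad: Array | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for child in node._children:
                if child.requires_grad and id(child) not in seen:
                    stack.append((child, False))
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, float)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: Array) -> None:
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._make(out_data, tensors, backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g: Array) -> None:
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tensors, backward)


def segment_sum(x: Tensor, segment_ids: Array, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets given per-row ids."""
    x = as_tensor(x)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = np.zeros((num_segments,) + x.data.shape[1:])
    np.add.at(out_data, segment_ids, x.data)

    def backward(g: Array) -> None:
        x._accumulate(g[segment_ids])

    return Tensor._make(out_data, (x,), backward)


def segment_max(x: Tensor, ptr: Array) -> Tensor:
    """Per-group column-wise max over contiguous row groups.

    ``ptr`` holds group boundaries (len = n_groups + 1), as in batched-graph
    layouts.  Gradient flows to the first maximal entry per (group, column).
    """
    x = as_tensor(x)
    ptr = np.asarray(ptr, dtype=np.intp)
    n_groups = len(ptr) - 1
    out_data = np.empty((n_groups,) + x.data.shape[1:])
    argmax = np.empty((n_groups,) + x.data.shape[1:], dtype=np.intp)
    for g_id in range(n_groups):
        block = x.data[ptr[g_id] : ptr[g_id + 1]]
        out_data[g_id] = block.max(axis=0)
        argmax[g_id] = ptr[g_id] + block.argmax(axis=0)

    def backward(g: Array) -> None:
        buf = np.zeros_like(x.data)
        if x.data.ndim == 1:
            np.add.at(buf, argmax, g)
        else:
            cols = np.broadcast_to(np.arange(x.data.shape[1]), argmax.shape)
            np.add.at(buf, (argmax.ravel(), cols.ravel()), g.ravel())
        x._accumulate(buf)

    return Tensor._make(out_data, (x,), backward)


def segment_mean(x: Tensor, ptr: Array) -> Tensor:
    """Per-group column-wise mean over contiguous row groups."""
    x = as_tensor(x)
    ptr = np.asarray(ptr, dtype=np.intp)
    counts = np.diff(ptr).astype(np.float64)
    ids = np.repeat(np.arange(len(counts)), np.diff(ptr))
    total = segment_sum(x, ids, len(counts))
    return total / Tensor(counts[:, None] if x.ndim > 1 else counts)


def grad_check(fn: Callable[..., Tensor], inputs: Iterable[Tensor],
               eps: float = 1e-6) -> float:
    """Max relative error between autodiff and central finite differences.

    Test helper: ``fn`` maps the inputs to a scalar Tensor.
    """
    inputs = list(inputs)
    out = fn(*inputs)
    for t in inputs:
        t.grad = None
    out = fn(*inputs)
    out.backward()
    worst = 0.0
    for t in inputs:
        num = np.zeros_like(t.data)
        flat = t.data.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = fn(*inputs).data
            flat[i] = orig - eps
            lo = fn(*inputs).data
            flat[i] = orig
            num.ravel()[i] = (hi - lo) / (2 * eps)
        denom = np.maximum(np.abs(num) + np.abs(t.grad), 1e-8)
        worst = max(worst, float(np.max(np.abs(num - t.grad) / denom)))
    return worst
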