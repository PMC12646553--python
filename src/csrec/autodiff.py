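"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The model trains small ragged per-patient graphs, so a tape of Python-level
ops over modest dense arrays is fast enough and keeps every gradient exact
and inspectable.  Supported ops are exactly those the model needs: affine
maps, elementwise nonlinearities, softmax-style exp/sum, concatenation,
slicing and reductions.  Broadcasting follows NumPy semantics; gradients of
broadcast operands are summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class _NoGrad:
    enabled = False


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        self._prev = _NoGrad.enabled
        _NoGrad.enabled = True

    def __exit__(self, *exc):
        _NoGrad.enabled = self._prev
        return False


class Tensor:
    """An ndarray node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # so ndarray + Tensor defers to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad and not _NoGrad.enabled
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward, requires_grad):
        out = Tensor(data)
        if requires_grad and not _NoGrad.enabled:
            out.requires_grad = True
            out._parents = tuple(p for p in parents if isinstance(p, Tensor))
            out._backward = backward
        return out

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(grad, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(grad, b.shape))

        return self._make(out_data, (self, other), backward,
                          self.requires_grad or other.requires_grad)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad, a=self):
            if a.requires_grad:
                a._accum(-grad)

        return self._make(-self.data, (self,), backward, self.requires_grad)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(grad * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(grad * a.data, b.shape))

        return self._make(out_data, (self, other), backward,
                          self.requires_grad or other.requires_grad)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(grad / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-grad * a.data / (b.data ** 2), b.shape))

        return self._make(out_data, (self, other), backward,
                          self.requires_grad or other.requires_grad)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __matmul__(self, other):
        """Matrix product for the 2D/1D combinations the model uses."""
        other = self._coerce(other)
        a_d, b_d = self.data.ndim, other.data.ndim
        if a_d > 2 or b_d > 2:
            raise ValueError("matmul supports only 1D/2D operands")
        out_data = self.data @ other.data

        def backward(grad, a=self, b=other, a_d=a_d, b_d=b_d):
            g = np.asarray(grad)
            if a.requires_grad:
                if a_d == 2 and b_d == 2:
                    a._accum(g @ b.data.T)
                elif a_d == 2 and b_d == 1:      # (m,n)@(n,) -> (m,)
                    a._accum(np.outer(g, b.data))
                elif a_d == 1 and b_d == 2:      # (n,)@(n,p) -> (p,)
                    a._accum(b.data @ g)
                else:                            # (n,)@(n,) -> scalar
                    a._accum(g * b.data)
            if b.requires_grad:
                if a_d == 2 and b_d == 2:
                    b._accum(a.data.T @ g)
                elif a_d == 2 and b_d == 1:
                    b._accum(a.data.T @ g)
                elif a_d == 1 and b_d == 2:
                    b._accum(np.outer(a.data, g))
                else:
                    b._accum(g * a.data)

        return self._make(out_data, (self, other), backward,
                          self.requires_grad or other.requires_grad)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(grad, a=self, o=out_data):
            if a.requires_grad:
                a._accum(grad * o)

        return self._make(out_data, (self,), backward, self.requires_grad)

    def log(self):
        def backward(grad, a=self):
            if a.requires_grad:
                a._accum(grad / a.data)

        return self._make(np.log(self.data), (self,), backward, self.requires_grad)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(grad, a=self, o=out_data):
            if a.requires_grad:
                a._accum(grad * (1.0 - o ** 2))

        return self._make(out_data, (self,), backward, self.requires_grad)

    def sigmoid(self):
        out_data = np.where(self.data >= 0,
                            1.0 / (1.0 + np.exp(-np.clip(self.data, None, 60))),
                            np.exp(np.clip(self.data, -60, None))
                            / (1.0 + np.exp(np.clip(self.data, -60, None))))

        def backward(grad, a=self, o=out_data):
            if a.requires_grad:
                a._accum(grad * o * (1.0 - o))

        return self._make(out_data, (self,), backward, self.requires_grad)

    def tanhshrink(self):
        """x - tanh(x): near-linear for large |x|, cubic near the origin."""
        t = np.tanh(self.data)

        def backward(grad, a=self, t=t):
            if a.requires_grad:
                a._accum(grad * (t ** 2))

        return self._make(self.data - t, (self,), backward, self.requires_grad)

    def leaky_relu(self, negative_slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, negative_slope)

        def backward(grad, a=self, m=mask):
            if a.requires_grad:
                a._accum(grad * m)

        return self._make(self.data * mask, (self,), backward, self.requires_grad)

    def elu(self, alpha: float = 1.0):
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out_data = np.where(self.data > 0, self.data, neg)

        def backward(grad, a=self, neg=neg, alpha=alpha):
            if a.requires_grad:
                a._accum(grad * np.where(a.data > 0, 1.0, neg + alpha))

        return self._make(out_data, (self,), backward, self.requires_grad)

    def clip(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(grad, a=self, m=mask):
            if a.requires_grad:
                a._accum(grad * m)

        return self._make(np.clip(self.data, lo, hi), (self,), backward,
                          self.requires_grad)

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())

        return self._make(out_data, (self,), backward, self.requires_grad)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def backward(grad, a=self):
            if a.requires_grad:
                a._accum(np.asarray(grad).reshape(a.shape))

        return self._make(self.data.reshape(*shape), (self,), backward,
                          self.requires_grad)

    def __getitem__(self, idx):
        def backward(grad, a=self, idx=idx):
            if a.requires_grad:
                g = np.zeros_like(a.data)
                np.add.at(g, idx, grad)
                a._accum(g)

        return self._make(self.data[idx], (self,), backward, self.requires_grad)

    @property
    def T(self):
        def backward(grad, a=self):
            if a.requires_grad:
                a._accum(np.asarray(grad).T)

        return self._make(self.data.T, (self,), backward, self.requires_grad)

    # -- backward pass --------------------------------------------------------
    def _accum(self, grad):
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad = self.grad + grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad, ts=tensors, offs=offsets, axis=axis):
        g = np.asarray(grad)
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tensors, backward,
                        any(t.requires_grad for t in tensors))


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(grad, ts=tensors, axis=axis):
        g = np.asarray(grad)
        for i, t in enumerate(ts):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tensors, backward,
                        any(t.requires_grad for t in tensors))
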