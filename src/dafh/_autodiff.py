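"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine supports exactly the operations the hashing network needs:
broadcasting arithmetic, matrix products, stride-1 2-D convolution, 2x2
average pooling, axis reductions (sum / mean / max), elementwise
nonlinearities, reshape and concatenation.  Gradients are accumulated in
float64 throughout so that training runs are bit-reproducible on CPU.

A :class:`Tensor` wraps an ``ndarray`` and records the closure that
propagates the adjoint to its parents; :meth:`Tensor.backward` walks the
graph in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "avg_pool2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray):
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def bwd(g):
            self._accumulate(g)
            other._accumulate(g)

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def bwd(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data ** e

        def bwd(g):
            base = self.data
            # derivative e*x^(e-1); define 0 where both value and slope vanish
            with np.errstate(divide="ignore", invalid="ignore"):
                d = e * base ** (e - 1.0)
            d = np.where(np.isfinite(d), d, 0.0)
            self._accumulate(g * d)

        return self._make(out_data, (self,), bwd)

    def __matmul__(self, other):
        other = self._coerce(other)

        def bwd(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bwd)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out_data)

        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accumulate(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), bwd)

    def clamp(self, lo: float, hi: float):
        """Clip values; the gradient is zero outside [lo, hi]."""
        mask = (self.data >= lo) & (self.data <= hi)

        def bwd(g):
            self._accumulate(g * mask)

        return self._make(np.clip(self.data, lo, hi), (self,), bwd)

    def softplus(self):
        # numerically stable log(1 + exp(x))
        out_data = np.logaddexp(0.0, self.data)

        def bwd(g):
            self._accumulate(g / (1.0 + np.exp(-self.data)))

        return self._make(out_data, (self,), bwd)

    def sqrt(self):
        return self ** 0.5

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return self._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max reduction; ties route the gradient to the first maximizer."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        arg = self.data.argmax(axis=axis)

        def bwd(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            gi = np.zeros_like(self.data)
            idx = list(np.indices(arg.shape))
            idx.insert(axis if axis >= 0 else self.data.ndim + axis, arg)
            gi[tuple(idx)] = np.squeeze(g, axis=axis)
            self._accumulate(gi)

        return self._make(out_data, (self,), bwd)

    def take(self, indices) -> "Tensor":
        """Gather rows along axis 0 (duplicate indices accumulate gradient)."""
        idx = np.asarray(indices, dtype=np.intp)

        def bwd(g):
            gi = np.zeros_like(self.data)
            np.add.at(gi, idx, g)
            self._accumulate(gi)

        return self._make(self.data[idx], (self,), bwd)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            self._accumulate(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bwd)

    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), bwd)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int = 0) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), NCHW / OIHW layout."""
    n, c, h, ww = x.shape
    o, ci, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, kernel {ci}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho, wo = h + 2 * pad - kh + 1, ww + 2 * pad - kw + 1
    out = np.zeros((n, o, ho, wo))
    for i in range(kh):
        for j in range(kw):
            out += np.einsum(
                "nchw,oc->nohw", xp[:, :, i : i + ho, j : j + wo], w.data[:, :, i, j],
                optimize=True,
            )
    if b is not None:
        out += b.data.reshape(1, o, 1, 1)

    def bwd(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, :, i : i + ho, j : j + wo]
                gw[:, :, i, j] = np.einsum("nohw,nchw->oc", g, patch, optimize=True)
                gxp[:, :, i : i + ho, j : j + wo] += np.einsum(
                    "nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True
                )
        gx = gxp[:, :, pad : pad + h, pad : pad + ww] if pad else gxp
        x._accumulate(gx)
        w._accumulate(gw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, bwd)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k average pooling; spatial dims must divide k."""
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims ({h},{w}) not divisible by pool size {k}")
    out = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def bwd(g):
        gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        x._accumulate(gx)

    return Tensor._make(out, (x,), bwd)
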