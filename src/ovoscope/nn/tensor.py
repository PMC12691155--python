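"""A minimal reverse-mode autodiff engine on numpy arrays.

Supports exactly the operations needed by the residual/attention networks in
this package: broadcasting elementwise arithmetic, matmul, reductions
(sum/mean/max), shape ops, sigmoid/relu/clip, 2-D convolution and max-pooling
(both via im2col with a vectorised col2im scatter), and fused softmax
cross-entropy. Everything is float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "maxpool2d", "softmax_cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # keep numpy from hijacking ndarray (op) Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this node (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep ResNets overflow recursion limits
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
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = any(p.requires_grad for p in parents)
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- elementwise arithmetic -------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.shape)
            )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return self._make(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            self._accumulate(g * mask)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = g
            if not keepdims and axis is not None:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        expanded = (
            out_data
            if keepdims or axis is None
            else np.expand_dims(out_data, axis)
        )
        mask = self.data == expanded
        counts = mask.sum(axis=axis, keepdims=True)

        def backward(g):
            gg = g
            if not keepdims and axis is not None:
                gg = np.expand_dims(gg, axis)
            self._accumulate(mask * (gg / counts))  # split ties evenly

        return self._make(out_data, (self,), backward)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        old_shape = self.shape

        def backward(g):
            self._accumulate(g.reshape(old_shape))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inverse = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inverse))

        return self._make(self.data.transpose(axes), (self,), backward)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    """Concatenate along `axis`, splitting the gradient back."""
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            index = [slice(None)] * g.ndim
            index[axis] = slice(a, b)
            t._accumulate(g[tuple(index)])

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad or t._parents for t in tensors):
        out.requires_grad = any(t.requires_grad for t in tensors)
        out._parents = tuple(tensors)
        out._backward = backward
    return out


# -- convolution / pooling -------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N,C,H,W) -> windows (N, C, kh, kw, Ho, Wo); returns (col, Ho, Wo)."""
    n, c, h, w = x.shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    col = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            col[:, :, i, j] = x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return col, ho, wo


def _col2im(dcol: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    """Scatter-add window gradients back onto the (padded) input."""
    n, c, h, w = x_shape
    ho, wo = dcol.shape[-2:]
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcol.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcol[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, fused forward/backward."""
    cout, cin, kh, kw = weight.shape
    if x.shape[1] != cin:
        raise ValueError(f"expected {cin} input channels, got {x.shape[1]}")
    col, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    n = x.shape[0]
    col_mat = col.reshape(n, cin * kh * kw, ho * wo)
    w_mat = weight.data.reshape(cout, cin * kh * kw)
    out_data = (w_mat @ col_mat).reshape(n, cout, ho, wo)
    if bias is not None:
        out_data += bias.data.reshape(1, cout, 1, 1)

    def backward(g):
        g_mat = g.reshape(n, cout, ho * wo)
        dw = np.einsum("nol,nkl->ok", g_mat, col_mat, optimize=True)
        weight._accumulate(dw.reshape(weight.shape))
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:  # skip dx for leaf inputs (images)
            dcol = (w_mat.T @ g_mat).reshape(n, cin, kh, kw, ho, wo)
            x._accumulate(_col2im(dcol, x.data.shape, kh, kw, stride, padding))

    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def maxpool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    """Max pooling (NCHW). Padded positions use -inf and never win."""
    n, c, h, w = x.shape
    ho = (h + 2 * padding - kernel) // stride + 1
    wo = (w + 2 * padding - kernel) // stride + 1
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    col = np.empty((n, c, kernel * kernel, ho, wo), dtype=x.data.dtype)
    k = 0
    for i in range(kernel):
        for j in range(kernel):
            col[:, :, k] = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
            k += 1
    argmax = col.argmax(axis=2)
    out_data = np.take_along_axis(col, argmax[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        dcol = np.zeros_like(col)
        np.put_along_axis(dcol, argmax[:, :, None], g[:, :, None], axis=2)
        dcol = dcol.reshape(n, c, kernel, kernel, ho, wo)
        x._accumulate(_col2im(dcol, x.data.shape, kernel, kernel, stride, padding))

    out = Tensor(out_data)
    if x.requires_grad or x._parents:
        out.requires_grad = x.requires_grad
        out._parents = (x,)
        out._backward = backward
    return out


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer class targets, fused with softmax."""
    targets = np.asarray(targets)
    n = logits.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    nll = -np.log(np.maximum(probs[np.arange(n), targets], 1e-12))
    loss = float(nll.mean())

    def backward(g):
        d = probs.copy()
        d[np.arange(n), targets] -= 1.0
        logits._accumulate(d * (g / n))

    out = Tensor(loss)
    if logits.requires_grad or logits._parents:
        out.requires_grad = logits.requires_grad
        out._parents = (logits,)
        out._backward = backward
    return out
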