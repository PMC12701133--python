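"""Minimal reverse-mode automatic differentiation on NumPy arrays.

All neural components of the package (detection backbone, detection head,
gated-attention LSTM classifier) are built on this module.  It implements a
small, strictly float64 tensor type with a dynamically built computation
graph and reverse-mode backpropagation — enough expressive power for
convolutions, recurrences and the attention/gating arithmetic used here,
while staying fully deterministic and dependency-free.

Design notes
------------
* ``Tensor.data`` is always a ``float64`` ndarray; gradients accumulate in
  ``Tensor.grad`` with the same shape.
* Broadcasting follows NumPy semantics; gradients of broadcast operands are
  summed back to the operand's shape (:func:`_unbroadcast`).
* Graph nodes hold closures; :meth:`Tensor.backward` runs a topological
  sort and calls them in reverse order.  No graph retention across calls.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack", "conv2d", "upsample_bicubic"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading dims added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum dims that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=False)


class Tensor:
    """A float64 array node in a reverse-mode autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative post-order topological sort
        order, seen = [], set()
        stack_ = [(self, False)]
        while stack_:
            node, expanded = stack_.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack_.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _accum(t: "Tensor", g: np.ndarray):
        if not t.requires_grad:
            return
        if t.grad is None:
            t.grad = g.copy()
        else:
            t.grad += g

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            Tensor._accum(self, _unbroadcast(g, self.data.shape))
            Tensor._accum(other, _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            Tensor._accum(self, -g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            Tensor._accum(self, _unbroadcast(g * other.data, self.data.shape))
            Tensor._accum(other, _unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            Tensor._accum(self, _unbroadcast(g / other.data, self.data.shape))
            Tensor._accum(
                other,
                _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data ** e

        def backward(g):
            Tensor._accum(self, g * e * self.data ** (e - 1.0))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                ga, gb = g * b, g * a
            elif a.ndim == 1:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.outer(a, g) if b.ndim == 2 else a[:, None] * g[..., None, :]
            elif b.ndim == 1:
                ga = g[..., None] * b
                gb = np.swapaxes(a, -1, -2) @ g if a.ndim == 2 else (
                    np.swapaxes(a, -1, -2) @ g[..., None]
                ).sum(axis=tuple(range(a.ndim - 2)))[..., 0]
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
            Tensor._accum(self, _unbroadcast(np.asarray(ga), a.shape))
            Tensor._accum(other, _unbroadcast(np.asarray(gb), b.shape))

        return self._make(out_data, (self, other), backward)

    # ----------------------------------------------------------- elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            Tensor._accum(self, g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            Tensor._accum(self, g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            Tensor._accum(self, g * 0.5 / out_data)

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            Tensor._accum(self, g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 0.5 * (np.tanh(0.5 * self.data) + 1.0)

        def backward(g):
            Tensor._accum(self, g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            Tensor._accum(self, g * mask)

        return self._make(self.data * mask, (self,), backward)

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)

        def backward(g):
            Tensor._accum(self, g * 0.5 * (np.tanh(0.5 * self.data) + 1.0))

        return self._make(out_data, (self,), backward)

    def smooth_l1(self, beta: float = 1.0):
        """Huber-style smooth-L1 applied elementwise."""
        x = self.data
        absx = np.abs(x)
        quad = absx < beta
        out_data = np.where(quad, 0.5 * x ** 2 / beta, absx - 0.5 * beta)

        def backward(g):
            Tensor._accum(self, g * np.where(quad, x / beta, np.sign(x)))

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                Tensor._accum(self, np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(
                    g, axis if isinstance(axis, tuple) else (axis,))
            Tensor._accum(self, np.broadcast_to(gg, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.data.shape[a] for a in axis]))
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def softmax(self, axis: int = -1):
        shifted = self - np.max(self.data, axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.data.shape

        def backward(g):
            Tensor._accum(self, g.reshape(old_shape))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            Tensor._accum(self, g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            Tensor._accum(self, full)

        return self._make(out_data, (self,), backward)


# ---------------------------------------------------------------- functions
def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            Tensor._accum(t, g[tuple(sl)])

    out = Tensor(out_data, requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            Tensor._accum(t, np.take(g, i, axis=axis))

    out = Tensor(out_data, requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out


# ------------------------------------------------------------- convolution
def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    b, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, (b, c, kh, kw, oh, ow), (s0, s1, s2, s3, s2 * stride, s3 * stride))
    return np.ascontiguousarray(windows).reshape(b, c * kh * kw, oh * ow)


def _col2im(cols: np.ndarray, xshape, kh: int, kw: int, stride: int,
            oh: int, ow: int) -> np.ndarray:
    b, c, h, w = xshape
    dx = np.zeros(xshape, dtype=np.float64)
    cols = cols.reshape(b, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += \
                cols[:, :, i, j]
    return dx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, im2col implementation."""
    x = _as_tensor(x)
    weight = _as_tensor(weight)
    b, cin, h, w = x.data.shape
    cout, cin_w, kh, kw = weight.data.shape
    if cin != cin_w:
        raise ValueError(
            f"channel mismatch: input has {cin}, kernel expects {cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    hp, wp = xp.shape[2], xp.shape[3]
    if hp < kh or wp < kw:
        raise ValueError(f"input {h}x{w} too small for {kh}x{kw} kernel")
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    cols = _im2col(xp, kh, kw, stride)                     # (B, C*kh*kw, L)
    wmat = weight.data.reshape(cout, -1)                   # (Cout, C*kh*kw)
    out_data = np.einsum("ok,bkl->bol", wmat, cols).reshape(b, cout, oh, ow)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gflat = g.reshape(b, cout, oh * ow)
        if weight.requires_grad:
            gw = np.einsum("bol,bkl->ok", gflat, cols).reshape(weight.data.shape)
            Tensor._accum(weight, gw)
        if bias is not None and bias.requires_grad:
            Tensor._accum(bias, g.sum(axis=(0, 2, 3)).reshape(bias.data.shape))
        if x.requires_grad:
            dcols = np.einsum("ok,bol->bkl", wmat, gflat)
            dxp = _col2im(dcols, (b, cin, hp, wp), kh, kw, stride, oh, ow)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            Tensor._accum(x, dxp)

    out = Tensor(out_data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = parents
        out._backward = backward
    return out


# --------------------------------------------------------- cubic upsampling
def _cubic_weight(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Cubic convolution kernel (Keys / Catmull-Rom for a=-0.5)."""
    t = np.abs(t)
    w = np.zeros_like(t)
    m1 = t <= 1
    m2 = (t > 1) & (t < 2)
    w[m1] = (a + 2) * t[m1] ** 3 - (a + 3) * t[m1] ** 2 + 1
    w[m2] = a * t[m2] ** 3 - 5 * a * t[m2] ** 2 + 8 * a * t[m2] - 4 * a
    return w


def upsample_matrix(n_in: int, factor: int) -> np.ndarray:
    """(n_in*factor, n_in) cubic-convolution interpolation matrix.

    Half-pixel centre alignment; out-of-range taps are clamped to the edge
    sample with their weights accumulated, so each row sums to exactly 1 and
    constants are reproduced bit-exactly.
    """
    n_out = n_in * factor
    mat = np.zeros((n_out, n_in), dtype=np.float64)
    for o in range(n_out):
        src = (o + 0.5) / factor - 0.5
        base = int(np.floor(src))
        for k in range(-1, 3):
            i = base + k
            w = _cubic_weight(np.asarray(src - i))
            mat[o, min(max(i, 0), n_in - 1)] += float(w)
    # enforce exact partition of unity against accumulated rounding
    mat /= mat.sum(axis=1, keepdims=True)
    return mat


def upsample_bicubic(x: Tensor, factor: int) -> Tensor:
    """Bicubic (cubic-convolution) upsampling of an NCHW map by 2x or 3x."""
    if factor not in (2, 3):
        raise ValueError(f"upsampling factor must be 2 or 3, got {factor}")
    x = _as_tensor(x)
    b, c, h, w = x.data.shape
    wh = upsample_matrix(h, factor)
    ww = upsample_matrix(w, factor)
    out_data = np.einsum("oh,bchw,pw->bcop", wh, x.data, ww)

    def backward(g):
        Tensor._accum(x, np.einsum("oh,bcop,pw->bchw", wh, g, ww))

    out = Tensor(out_data, requires_grad=x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)
        out._backward = backward
    return out
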