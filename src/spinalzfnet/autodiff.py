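"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray`` and
records, per elementary operation, closures that map the upstream gradient to
contributions on each parent.  ``Tensor.backward`` runs a topological sweep.
Everything the network modules need — broadcasting arithmetic, matmul,
2-D (transposed) convolution, non-overlapping max pooling with indices and
the matching unpooling — is provided here; composite layers (batch norm,
PReLU, local response normalisation, losses) are built from these primitives
in :mod:`spinalzfnet.nn` so their gradients come for free.

All data is float64: the engine is sized for desk-scale experiments where
numerical transparency (e.g. finite-difference gradient checks) matters more
than throughput.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "maxpool2d",
    "max_unpool2d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        # sequence of (parent Tensor, fn(upstream) -> grad contribution)
        self._parents = tuple(parents)

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order via iterative DFS
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            for parent, fn in node._parents:
                contrib = fn(g)
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + contrib
                else:
                    grads[key] = contrib

    # -- helpers -----------------------------------------------------------
    def _needs(self) -> bool:
        return self.requires_grad or bool(self._parents)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data
        parents = []
        if self._needs():
            parents.append((self, lambda g, s=self.shape: _unbroadcast(g, s)))
        if other._needs():
            parents.append((other, lambda g, s=other.shape: _unbroadcast(g, s)))
        return Tensor(out_data, parents=parents)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data
        parents = []
        if self._needs():
            parents.append((self, lambda g, o=other.data, s=self.shape: _unbroadcast(g * o, s)))
        if other._needs():
            parents.append((other, lambda g, o=self.data, s=other.shape: _unbroadcast(g * o, s)))
        return Tensor(out_data, parents=parents)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out_data = self.data ** exponent
        parents = []
        if self._needs():
            parents.append(
                (self, lambda g, x=self.data, e=exponent: g * e * x ** (e - 1.0))
            )
        return Tensor(out_data, parents=parents)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        parents = []
        if self._needs():
            parents.append((self, lambda g, o=out_data: g * o))
        return Tensor(out_data, parents=parents)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)
        parents = []
        if self._needs():
            parents.append((self, lambda g, x=self.data: g / x))
        return Tensor(out_data, parents=parents)

    def relu(self) -> "Tensor":
        mask = self.data > 0
        parents = []
        if self._needs():
            parents.append((self, lambda g, m=mask: g * m))
        return Tensor(self.data * mask, parents=parents)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        parents = []
        if self._needs():
            parents.append((self, lambda g, o=out_data: g * o * (1.0 - o)))
        return Tensor(out_data, parents=parents)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)
        parents = []
        if self._needs():
            parents.append((self, lambda g, o=out_data: g * (1.0 - o * o)))
        return Tensor(out_data, parents=parents)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        parents = []
        if self._needs():
            parents.append((self, lambda g, s=self.shape: g.reshape(s)))
        return Tensor(out_data, parents=parents)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)
        parents = []
        if self._needs():
            parents.append((self, lambda g, i=tuple(inv): g.transpose(i)))
        return Tensor(out_data, parents=parents)

    def __getitem__(self, key) -> "Tensor":
        out_data = self.data[key]

        def _grad(g, key=key, shape=self.shape):
            full = np.zeros(shape)
            full[key] = g
            return full

        parents = [(self, _grad)] if self._needs() else []
        return Tensor(out_data, parents=parents)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def _grad(g, axis=axis, keepdims=keepdims, shape=self.shape):
            if axis is None:
                return np.broadcast_to(g, shape).copy()
            if not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, shape).copy()

        parents = [(self, _grad)] if self._needs() else []
        return Tensor(out_data, parents=parents)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data
        parents = []
        if self._needs():
            parents.append((self, lambda g, o=other.data: g @ o.T))
        if other._needs():
            parents.append((other, lambda g, o=self.data: o.T @ g))
        return Tensor(out_data, parents=parents)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={'set' if self.grad is not None else 'none'})"


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    parents = []
    offset = 0
    for t in tensors:
        size = t.shape[axis]

        def _grad(g, start=offset, stop=offset + size, axis=axis):
            index = [slice(None)] * g.ndim
            index[axis] = slice(start, stop)
            return g[tuple(index)]

        if t._needs():
            parents.append((t, _grad))
        offset += size
    return Tensor(out_data, parents=parents)


# ---------------------------------------------------------------------------
# convolution primitives (NCHW layout)
# ---------------------------------------------------------------------------

def _pad_hw(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: tuple[int, int] | int = 0,
           dilation: int = 1) -> Tensor:
    """Cross-correlation of ``x`` (N,C,H,W) with ``w`` (O,C,kh,kw).

    Implemented as a sum of strided-slice/tensordot terms, one per kernel
    tap — efficient for the small kernels used here and trivially
    differentiable by running the same loop in reverse.
    """
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.shape
    o, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    s, d = stride, dilation
    ho = (h + 2 * ph - d * (kh - 1) - 1) // s + 1
    wo = (wd + 2 * pw - d * (kw - 1) - 1) // s + 1
    xp = _pad_hw(x.data, ph, pw)
    out = np.zeros((n, o, ho, wo))
    for a in range(kh):
        for bb in range(kw):
            xs = xp[:, :, a * d: a * d + ho * s: s, bb * d: bb * d + wo * s: s]
            out += np.einsum("nchw,oc->nohw", xs, w.data[:, :, a, bb], optimize=True)
    if b is not None:
        out += b.data.reshape(1, o, 1, 1)

    parents = []
    if x._needs():
        def _gx(g, w_data=w.data, shape=x.shape, ph=ph, pw=pw, s=s, d=d,
                kh=kh, kw=kw, ho=ho, wo=wo):
            n_, c_, h_, w_ = shape
            gxp = np.zeros((n_, c_, h_ + 2 * ph, w_ + 2 * pw))
            for a in range(kh):
                for bb in range(kw):
                    gxp[:, :, a * d: a * d + ho * s: s, bb * d: bb * d + wo * s: s] += \
                        np.einsum("nohw,oc->nchw", g, w_data[:, :, a, bb], optimize=True)
            if ph or pw:
                gxp = gxp[:, :, ph: ph + h_, pw: pw + w_]
            return gxp
        parents.append((x, _gx))
    if w._needs():
        def _gw(g, xp=xp, shape=w.shape, s=s, d=d, ho=ho, wo=wo):
            o_, c_, kh_, kw_ = shape
            gw = np.zeros(shape)
            for a in range(kh_):
                for bb in range(kw_):
                    xs = xp[:, :, a * d: a * d + ho * s: s, bb * d: bb * d + wo * s: s]
                    gw[:, :, a, bb] = np.einsum("nohw,nchw->oc", g, xs, optimize=True)
            return gw
        parents.append((w, _gw))
    if b is not None and b._needs():
        parents.append((b, lambda g: g.sum(axis=(0, 2, 3))))
    return Tensor(out, parents=parents)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 1, padding: int = 0,
                     output_padding: int = 0) -> Tensor:
    """Transposed convolution; ``w`` has shape (C_in, C_out, kh, kw)."""
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.shape
    c2, o, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    s, p, op = stride, padding, output_padding
    hf, wf = (h - 1) * s + kh, (wd - 1) * s + kw      # full (uncropped) size
    ho, wo = (h - 1) * s - 2 * p + kh + op, (wd - 1) * s - 2 * p + kw + op
    if p + ho > hf or p + wo > wf:
        raise ValueError("output_padding too large for this kernel/stride")
    full = np.zeros((n, o, hf, wf))
    for a in range(kh):
        for bb in range(kw):
            full[:, :, a: a + (h - 1) * s + 1: s, bb: bb + (wd - 1) * s + 1: s] += \
                np.einsum("nchw,co->nohw", x.data, w.data[:, :, a, bb], optimize=True)
    out = full[:, :, p: p + ho, p: p + wo]
    if b is not None:
        out = out + b.data.reshape(1, o, 1, 1)

    def _full_grad(g):
        gfull = np.zeros((n, g.shape[1], hf, wf))
        gfull[:, :, p: p + ho, p: p + wo] = g
        return gfull

    parents = []
    if x._needs():
        def _gx(g, w_data=w.data):
            gfull = _full_grad(g)
            gx = np.zeros((n, c, h, wd))
            for a in range(kh):
                for bb in range(kw):
                    gs = gfull[:, :, a: a + (h - 1) * s + 1: s, bb: bb + (wd - 1) * s + 1: s]
                    gx += np.einsum("nohw,co->nchw", gs, w_data[:, :, a, bb], optimize=True)
            return gx
        parents.append((x, _gx))
    if w._needs():
        def _gw(g, x_data=x.data):
            gfull = _full_grad(g)
            gw = np.zeros(w.shape)
            for a in range(kh):
                for bb in range(kw):
                    gs = gfull[:, :, a: a + (h - 1) * s + 1: s, bb: bb + (wd - 1) * s + 1: s]
                    gw[:, :, a, bb] = np.einsum("nchw,nohw->co", x_data, gs, optimize=True)
            return gw
        parents.append((w, _gw))
    if b is not None and b._needs():
        parents.append((b, lambda g: g.sum(axis=(0, 2, 3))))
    return Tensor(out, parents=parents)


def maxpool2d(x: Tensor, kernel: int = 2) -> tuple[Tensor, np.ndarray]:
    """Non-overlapping max pooling (kernel == stride).

    Returns the pooled tensor and an integer index array (N,C,Ho,Wo) giving
    the argmax position within each window, consumable by
    :func:`max_unpool2d` — the index plumbing the encoder/decoder pairing
    relies on.
    """
    x = as_tensor(x)
    n, c, h, w = x.shape
    k = kernel
    if h % k or w % k:
        raise ValueError(f"pooling requires dimensions divisible by {k}")
    ho, wo = h // k, w // k
    windows = x.data.reshape(n, c, ho, k, wo, k).transpose(0, 1, 2, 4, 3, 5) \
        .reshape(n, c, ho, wo, k * k)
    idx = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def _grad(g, idx=idx):
        gw = np.zeros((n, c, ho, wo, k * k))
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        return gw.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)

    parents = [(x, _grad)] if x._needs() else []
    return Tensor(out, parents=parents), idx


def max_unpool2d(x: Tensor, indices: np.ndarray, kernel: int = 2) -> Tensor:
    """Place each value at the argmax position recorded by the paired pooling."""
    x = as_tensor(x)
    n, c, ho, wo = x.shape
    k = kernel
    if indices.shape != (n, c, ho, wo):
        raise ValueError("unpooling indices do not match input shape")
    out_windows = np.zeros((n, c, ho, wo, k * k))
    np.put_along_axis(out_windows, indices[..., None], x.data[..., None], axis=-1)
    out = out_windows.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5) \
        .reshape(n, c, ho * k, wo * k)

    def _grad(g, indices=indices):
        gw = g.reshape(n, c, ho, k, wo, k).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, k * k)
        return np.take_along_axis(gw, indices[..., None], axis=-1)[..., 0]

    parents = [(x, _grad)] if x._needs() else []
    return Tensor(out, parents=parents)
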