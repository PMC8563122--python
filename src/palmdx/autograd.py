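"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float32 ``ndarray`` and records the operations
applied to it on a tape; :meth:`Tensor.backward` walks the tape in reverse
topological order and accumulates gradients.  Only the operations needed by
the attention network are provided (elementwise arithmetic, activations,
2-D convolution via im2col, pooling, bilinear resizing, channel
concatenation, reductions, softmax).  Gradients are stored on every node of
the graph, which is what lets Grad-CAM read the gradient of a class score
with respect to an intermediate feature map.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _as_array(x) -> np.ndarray:
    # float64 arrays/scalars are preserved (used for scalar loss weights
    # where float32 granularity is too coarse); everything else is float32
    if isinstance(x, (np.ndarray, np.float64)) and np.asarray(x).dtype == np.float64:
        return np.asarray(x)
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"

    # -- graph walk --------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
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
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad = self.grad + g

    # -- elementwise arithmetic --------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def bw(g, a=self, b=other):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g, a=self):
            a._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def bw(g, a=self, b=other):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other.pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        out_data = self.data ** p

        def bw(g, a=self):
            a._accum(g * p * a.data ** (p - 1.0))

        return Tensor(out_data, parents=(self,), backward=bw)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bw(g, a=self, y=out_data):
            a._accum(g * y)

        return Tensor(out_data, parents=(self,), backward=bw)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def bw(g, a=self):
            a._accum(g / a.data)

        return Tensor(out_data, parents=(self,), backward=bw)

    def clip(self, lo: float, hi: float) -> "Tensor":
        out_data = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)

        def bw(g, a=self, m=mask):
            a._accum(g * m)

        return Tensor(out_data, parents=(self,), backward=bw)

    # -- activations -------------------------------------------------------
    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)
        mask = self.data > 0.0

        def bw(g, a=self, m=mask):
            a._accum(g * m)

        return Tensor(out_data, parents=(self,), backward=bw)

    def sigmoid(self) -> "Tensor":
        # clamp the output away from exactly 0/1 so attention masks stay in
        # the open unit interval even for saturating pre-activations
        z = np.clip(self.data, -80.0, 80.0)
        out_data = np.clip(1.0 / (1.0 + np.exp(-z)), 1e-12, 1.0 - 1e-7)

        def bw(g, a=self, y=out_data):
            a._accum(g * y * (1.0 - y))

        return Tensor(out_data, parents=(self,), backward=bw)

    # -- shape / indexing --------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        out_data = self.data.reshape(*shape)

        def bw(g, a=self, s=old):
            a._accum(g.reshape(s))

        return Tensor(out_data, parents=(self,), backward=bw)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def bw(g, a=self, i=idx):
            buf = np.zeros_like(a.data)
            np.add.at(buf, i, g)
            a._accum(buf)

        return Tensor(out_data, parents=(self,), backward=bw)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g, a=self, ax=axis, kd=keepdims):
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, a.data.shape).astype(np.float32))

        return Tensor(out_data, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        scale = Tensor(np.asarray(1.0 / n, dtype=self.data.dtype))
        return self.sum(axis=axis, keepdims=keepdims) * scale

    # -- softmax -----------------------------------------------------------
    def softmax(self, axis: int = 1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def bw(g, a=self, y=y, ax=axis):
            dot = (g * y).sum(axis=ax, keepdims=True)
            a._accum(y * (g - dot))

        return Tensor(y, parents=(self,), backward=bw)

    # -- spatial ops (NCHW) -------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """2-D convolution (cross-correlation) for NCHW input.

        ``weight`` has shape (O, C, kh, kw).
        """
        x, w = self.data, weight.data
        n, c, h, wdt = x.shape
        o, c2, kh, kw = w.shape
        if c != c2:
            raise ValueError(f"conv2d channel mismatch: input {c}, kernel {c2}")
        hp = (h + 2 * padding - kh) // stride + 1
        wp = (wdt + 2 * padding - kw) // stride + 1
        cols = _im2col(x, kh, kw, stride, padding, hp, wp)  # (n, c*kh*kw, hp*wp)
        w2 = w.reshape(o, c * kh * kw)
        out = np.einsum("ok,nkp->nop", w2, cols, optimize=True)
        out = out.reshape(n, o, hp, wp)
        if bias is not None:
            out = out + bias.data.reshape(1, o, 1, 1)

        parents = (self, weight) if bias is None else (self, weight, bias)

        def bw(g, a=self, wt=weight, bt=bias, cols=cols, w2=w2):
            gf = g.reshape(n, o, hp * wp)
            gw = np.einsum("nop,nkp->ok", gf, cols, optimize=True)
            wt._accum(gw.reshape(o, c, kh, kw))
            if bt is not None:
                bt._accum(g.sum(axis=(0, 2, 3)))
            gcols = np.einsum("ok,nop->nkp", w2, gf, optimize=True)
            a._accum(_col2im(gcols, x.shape, kh, kw, stride, padding, hp, wp))

        return Tensor(out, parents=parents, backward=bw)

    def avg_pool2d(self, k: int = 2) -> "Tensor":
        n, c, h, w = self.data.shape
        if h % k or w % k:
            raise ValueError(f"avg_pool2d: spatial size ({h},{w}) not divisible by {k}")
        out = self.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

        def bw(g, a=self):
            gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            a._accum(gx)

        return Tensor(out, parents=(self,), backward=bw)

    def global_avg_pool(self) -> "Tensor":
        """(N, C, H, W) -> (N, C) spatial mean."""
        return self.mean(axis=(2, 3))

    def bilinear_resize(self, out_h: int, out_w: int) -> "Tensor":
        """Separable bilinear resize with align_corners=False convention."""
        n, c, h, w = self.data.shape
        ar = _bilinear_matrix(out_h, h)
        ac = _bilinear_matrix(out_w, w)
        out = np.einsum("oh,nchw,pw->ncop", ar, self.data, ac, optimize=True)

        def bw(g, a=self, ar=ar, ac=ac):
            a._accum(np.einsum("oh,ncop,pw->nchw", ar, g, ac, optimize=True))

        return Tensor(out, parents=(self,), backward=bw)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g, ts=tuple(tensors), off=offsets, ax=axis):
        for i, t in enumerate(ts):
            sl = [slice(None)] * g.ndim
            sl[ax] = slice(off[i], off[i + 1])
            t._accum(g[tuple(sl)])

    return Tensor(out, parents=tuple(tensors), backward=bw)


# -- im2col helpers ---------------------------------------------------------

def _im2col(x, kh, kw, stride, padding, hp, wp):
    n, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, hp, wp),
        strides=(s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride),
        writeable=False,
    )
    return view.reshape(n, c * kh * kw, hp * wp).copy()


def _col2im(gcols, xshape, kh, kw, stride, padding, hp, wp):
    n, c, h, w = xshape
    gx = np.zeros((n, c, h + 2 * padding, w + 2 * padding), dtype=np.float32)
    g6 = gcols.reshape(n, c, kh, kw, hp, wp)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i:i + stride * hp:stride, j:j + stride * wp:stride] += g6[:, :, i, j]
    if padding:
        gx = gx[:, :, padding:-padding, padding:-padding]
    return gx


_BILINEAR_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    key = (n_out, n_in)
    m = _BILINEAR_CACHE.get(key)
    if m is None:
        m = np.zeros((n_out, n_in), dtype=np.float32)
        if n_in == 1:
            m[:, 0] = 1.0
        else:
            scale = n_in / n_out
            src = np.clip((np.arange(n_out) + 0.5) * scale - 0.5, 0, n_in - 1)
            lo = np.floor(src).astype(int)
            hi = np.minimum(lo + 1, n_in - 1)
            frac = (src - lo).astype(np.float32)
            m[np.arange(n_out), lo] += 1.0 - frac
            m[np.arange(n_out), hi] += frac
        _BILINEAR_CACHE[key] = m
    return m
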