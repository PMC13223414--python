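"""Reverse-mode automatic differentiation over numpy arrays.

This module provides the tensor, layer, and optimizer machinery that the
detector is built from: a tape-based :class:`Tensor` with broadcasting-aware
gradients, 2-D (grouped) convolution via im2col, batch/group normalization,
the bilinear boundary-sampling primitive used by the task-aligned head, and
an AdamW optimizer with per-parameter weight-decay exemption.

Everything is float32 and CPU-only; the networks trained here are small
enough that im2col + BLAS matmul is the right trade-off.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_FLOAT = np.float32

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference / oracles)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer to Tensor's reflected operators (e.g. ndarray - Tensor)
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_FLOAT)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def numpy(self) -> np.ndarray:
        """Detached copy of the values."""
        return np.array(self.data)

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- autograd -------------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.shape), dtype=_FLOAT)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        if grad is None:
            grad = np.ones(self.shape, dtype=_FLOAT)
        self._accumulate(np.asarray(grad, dtype=_FLOAT))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- operators ------------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # -- reductions / reshapes ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)


class Parameter(Tensor):
    """Trainable tensor; `no_decay` marks it exempt from weight decay."""

    __slots__ = ("no_decay",)

    def __init__(self, data, no_decay: bool = False):
        super().__init__(data, requires_grad=True)
        self.no_decay = no_decay


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: tuple[Tensor, ...],
          backward: Callable[[Tensor], None] | None) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        if backward is not None:
            out._backward = lambda: backward(out)
    return out


# ---------------------------------------------------------------------------
# elementwise primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def bw(out: Tensor) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(out.grad, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(out.grad, b.shape))

    return _make(data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def bw(out: Tensor) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(out.grad * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(out.grad * a.data, b.shape))

    return _make(data, (a, b), bw)


def power(a, p: float) -> Tensor:
    a = _as_tensor(a)
    data = np.power(a.data, p)

    def bw(out: Tensor) -> None:
        if a.requires_grad:
            a._accumulate(out.grad * p * np.power(a.data, p - 1.0))

    return _make(data, (a,), bw)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    data = np.exp(a.data)

    def bw(out: Tensor) -> None:
        if a.requires_grad:
            a._accumulate(out.grad * data)

    return _make(data, (a,), bw)


def log(a) -> Tensor:
    a = _as_tensor(a)
    data = np.log(a.data)

    def bw(out: Tensor) -> None:
        if a.requires_grad:
            a._accumulate(out.grad / a.data)

    return _make(data, (a,), bw)


def sqrt(a) -> Tensor:
    a = _as_tensor(a)
    data = np.sqrt(a.data)

    def bw(out: Tensor) -> None:
        if a.requires_grad:
            a._accumulate(out.grad * 0.5 / np.maximum(data, 1e-12))

    return _make(data, (a,), bw)


def clip(a, lo: float, hi: float) -> Tensor:
    a = _as_tensor(a)
    data = np.clip(a.data, lo, hi)

    def bw(out: Tensor) -> None:
        if a.requires_grad:
            mask = (a.data >= lo) & (a.data <= hi)
            a._accumulate(out.grad * mask)

    return _make(data, (a,), bw)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    data = np.maximum(a.data, 0.0)

    def bw(out: Tensor) -> None:
        if a.requires_grad:
            a._accumulate(out.grad * (a.data > 0.0))

    return _make(data, (a,), bw)


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    data = _stable_sigmoid(a.data)

    def bw(out: Tensor) -> None:
        if a.requires_grad:
            a._accumulate(out.grad * data * (1.0 - data))

    return _make(data, (a,), bw)


def silu(a) -> Tensor:
    """Swish / SiLU: x * sigmoid(x)."""
    a = _as_tensor(a)
    s = _stable_sigmoid(a.data)
    data = a.data * s

    def bw(out: Tensor) -> None:
        if a.requires_grad:
            a._accumulate(out.grad * (s * (1.0 + a.data * (1.0 - s))))

    return _make(data, (a,), bw)


def maximum(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = np.maximum(a.data, b.data)

    def bw(out: Tensor) -> None:
        mask = a.data >= b.data
        if a.requires_grad:
            a._accumulate(_unbroadcast(out.grad * mask, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(out.grad * (~mask), b.shape))

    return _make(data, (a, b), bw)


def minimum(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = np.minimum(a.data, b.data)

    def bw(out: Tensor) -> None:
        mask = a.data <= b.data
        if a.requires_grad:
            a._accumulate(_unbroadcast(out.grad * mask, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(out.grad * (~mask), b.shape))

    return _make(data, (a, b), bw)


# ---------------------------------------------------------------------------
# reductions / shape ops
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(out: Tensor) -> None:
        if not a.requires_grad:
            return
        g = out.grad
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % a.ndim for ax in axes)
            shape = tuple(1 if i in axes else s for i, s in enumerate(a.shape))
            g = g.reshape(shape)
        a._accumulate(np.broadcast_to(g, a.shape))

    return _make(data, (a,), bw)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    n = a.size if axis is None else np.prod(
        [a.shape[ax % a.ndim] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    data = a.data.reshape(shape)

    def bw(out: Tensor) -> None:
        if a.requires_grad:
            a._accumulate(out.grad.reshape(a.shape))

    return _make(data, (a,), bw)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def bw(out: Tensor) -> None:
        if a.requires_grad:
            a._accumulate(np.transpose(out.grad, inv))

    return _make(data, (a,), bw)


def getitem(a, idx) -> Tensor:
    a = _as_tensor(a)
    data = a.data[idx]

    def bw(out: Tensor) -> None:
        if a.requires_grad:
            g = np.zeros(a.shape, dtype=_FLOAT)
            np.add.at(g, idx, out.grad)
            a._accumulate(g)

    return _make(data, (a,), bw)


def take_rows(a, index: np.ndarray) -> Tensor:
    """Gather rows of a 2-D tensor; scatter-add on the way back."""
    a = _as_tensor(a)
    index = np.asarray(index, dtype=np.int64)
    data = a.data[index]

    def bw(out: Tensor) -> None:
        if a.requires_grad:
            g = np.zeros(a.shape, dtype=_FLOAT)
            np.add.at(g, index, out.grad)
            a._accumulate(g)

    return _make(data, (a,), bw)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(out: Tensor) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(out.grad[tuple(sl)])

    return _make(data, tuple(tensors), bw)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def bw(out: Tensor) -> None:
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(out.grad, i, axis=axis))

    return _make(data, tuple(tensors), bw)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def bw(out: Tensor) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(out.grad @ np.swapaxes(b.data, -1, -2), a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ out.grad, b.shape))

    return _make(data, (a, b), bw)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    n, c, _, _ = xp.shape
    cols = np.empty((n, c, k * k, ho * wo), dtype=xp.dtype)
    t = 0
    for di in range(k):
        for dj in range(k):
            patch = xp[:, :, di:di + stride * ho:stride, dj:dj + stride * wo:stride]
            cols[:, :, t, :] = patch.reshape(n, c, -1)
            t += 1
    return cols


def _col2im(cols: np.ndarray, xshape, k: int, stride: int, pad: int,
            ho: int, wo: int) -> np.ndarray:
    n, c, h, w = xshape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    t = 0
    for di in range(k):
        for dj in range(k):
            xp[:, :, di:di + stride * ho:stride, dj:dj + stride * wo:stride] += \
                cols[:, :, t, :].reshape(n, c, ho, wo)
            t += 1
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, pad: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D convolution; weight shape (C_out, C_in/groups, k, k)."""
    x = _as_tensor(x)
    n, c, h, w = x.shape
    cout, cg, k, _ = weight.shape
    assert c == cg * groups, "channel/group mismatch"
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    cols = _im2col(xp, k, stride, ho, wo)  # (N, C, k*k, L)
    g = groups
    l = ho * wo
    if g == 1:
        cols2 = cols.reshape(n, c * k * k, l)
        w2 = weight.data.reshape(cout, c * k * k)
        out = np.matmul(w2, cols2)                     # (N, Cout, L), BLAS
    elif cg == 1 and cout == c:
        # depthwise: batched (1 x k2) @ (k2 x L) per channel
        w2 = weight.data.reshape(1, c, 1, k * k)
        out = np.matmul(w2, cols).reshape(n, c, l)
    else:
        cols_g = cols.reshape(n, g, cg * k * k, l)
        w_g = weight.data.reshape(g, cout // g, cg * k * k)
        out = np.einsum("gok,ngkl->ngol", w_g, cols_g,
                        optimize=True).reshape(n, cout, l)
    out = out.reshape(n, cout, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)
    parents = (x, weight) + ((bias,) if bias is not None else ())

    def bw(o: Tensor) -> None:
        if bias is not None and bias.requires_grad:
            bias._accumulate(o.grad.sum(axis=(0, 2, 3)))
        if g == 1:
            gy = o.grad.reshape(n, cout, l)
            cols2 = cols.reshape(n, c * k * k, l)
            w2 = weight.data.reshape(cout, c * k * k)
            if weight.requires_grad:
                gw = np.matmul(gy, cols2.transpose(0, 2, 1)).sum(axis=0)
                weight._accumulate(gw.reshape(weight.shape))
            if x.requires_grad:
                gcols = np.matmul(w2.T, gy).reshape(n, c, k * k, l)
                x._accumulate(_col2im(gcols, x.shape, k, stride, pad, ho, wo))
        elif cg == 1 and cout == c:
            gy = o.grad.reshape(n, c, 1, l)
            if weight.requires_grad:
                gw = np.matmul(gy, cols.transpose(0, 1, 3, 2)).sum(axis=0)
                weight._accumulate(gw.reshape(weight.shape))
            if x.requires_grad:
                w2 = weight.data.reshape(1, c, k * k, 1)
                gcols = w2 * gy                        # (N, C, k2, L)
                x._accumulate(_col2im(gcols, x.shape, k, stride, pad, ho, wo))
        else:
            gy = o.grad.reshape(n, g, cout // g, l)
            cols_g = cols.reshape(n, g, cg * k * k, l)
            w_g = weight.data.reshape(g, cout // g, cg * k * k)
            if weight.requires_grad:
                gw = np.einsum("ngol,ngkl->gok", gy, cols_g, optimize=True)
                weight._accumulate(gw.reshape(weight.shape))
            if x.requires_grad:
                gcols = np.einsum("gok,ngol->ngkl", w_g, gy, optimize=True)
                gcols = gcols.reshape(n, c, k * k, l)
                x._accumulate(_col2im(gcols, x.shape, k, stride, pad, ho, wo))

    return _make(out, parents, bw)


def upsample_nearest2x(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bw(out: Tensor) -> None:
        if x.requires_grad:
            n, c, h2, w2 = out.grad.shape
            g = out.grad.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            x._accumulate(g)

    return _make(data, (x,), bw)


def boundary_sample(b: Tensor, o: Tensor) -> Tensor:
    """Bilinear re-sampling of a 4-channel boundary map at learned offsets.

    For boundary channel c and cell (i, j), samples b[:, c] at the continuous
    location (i + o[:, 2c], j + o[:, 2c+1]); coordinates are clamped to the
    map border. Gradients flow to both the map and the offsets.
    """
    b, o = _as_tensor(b), _as_tensor(o)
    n, c4, h, w = b.shape
    assert o.shape == (n, 2 * c4, h, w)
    ii, jj = np.meshgrid(np.arange(h, dtype=_FLOAT),
                         np.arange(w, dtype=_FLOAT), indexing="ij")
    out = np.empty_like(b.data)
    cache = []
    for c in range(c4):
        pi = ii[None] + o.data[:, 2 * c]
        pj = jj[None] + o.data[:, 2 * c + 1]
        in_i = (pi > 0.0) & (pi < h - 1.0) if h > 1 else np.zeros_like(pi, bool)
        in_j = (pj > 0.0) & (pj < w - 1.0) if w > 1 else np.zeros_like(pj, bool)
        pi = np.clip(pi, 0.0, h - 1.0)
        pj = np.clip(pj, 0.0, w - 1.0)
        i0 = np.floor(pi).astype(np.int64)
        j0 = np.floor(pj).astype(np.int64)
        i1 = np.minimum(i0 + 1, h - 1)
        j1 = np.minimum(j0 + 1, w - 1)
        wi = pi - i0
        wj = pj - j0
        plane = b.data[:, c]
        nn = np.arange(n)[:, None, None]
        v00 = plane[nn, i0, j0]
        v01 = plane[nn, i0, j1]
        v10 = plane[nn, i1, j0]
        v11 = plane[nn, i1, j1]
        out[:, c] = ((1 - wi) * (1 - wj) * v00 + (1 - wi) * wj * v01
                     + wi * (1 - wj) * v10 + wi * wj * v11)
        cache.append((i0, j0, i1, j1, wi, wj, v00, v01, v10, v11, in_i, in_j))

    def bw(res: Tensor) -> None:
        gb = np.zeros_like(b.data) if b.requires_grad else None
        go = np.zeros_like(o.data) if o.requires_grad else None
        nn = np.arange(n)[:, None, None]
        for c in range(c4):
            i0, j0, i1, j1, wi, wj, v00, v01, v10, v11, in_i, in_j = cache[c]
            g = res.grad[:, c]
            if gb is not None:
                np.add.at(gb[:, c], (nn, i0, j0), g * (1 - wi) * (1 - wj))
                np.add.at(gb[:, c], (nn, i0, j1), g * (1 - wi) * wj)
                np.add.at(gb[:, c], (nn, i1, j0), g * wi * (1 - wj))
                np.add.at(gb[:, c], (nn, i1, j1), g * wi * wj)
            if go is not None:
                dvi = (v10 - v00) * (1 - wj) + (v11 - v01) * wj
                dvj = (v01 - v00) * (1 - wi) + (v11 - v10) * wi
                go[:, 2 * c] = g * dvi * in_i
                go[:, 2 * c + 1] = g * dvj * in_j
        if gb is not None:
            b._accumulate(gb)
        if go is not None:
            o._accumulate(go)

    return _make(out, (b, o), bw)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self) -> Iterable[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def modules(self) -> Iterable["Module"]:
        yield self
        for _, child in self._children():
            yield from child.modules()

    def named_parameters(self, prefix: str = "") -> Iterable[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix=prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    # -- (de)serialization ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: np.array(p.data) for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                d[f"__bn{i}.mean"] = np.array(m.running_mean)
                d[f"__bn{i}.var"] = np.array(m.running_var)
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(d[name], dtype=_FLOAT).reshape(p.shape)
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(d[f"__bn{i}.mean"], dtype=_FLOAT)
                m.running_var = np.asarray(d[f"__bn{i}.var"], dtype=_FLOAT)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(_FLOAT)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int | None = None, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.groups = stride, groups
        self.pad = k // 2 if pad is None else pad
        fan_in = (cin // groups) * k * k
        self.weight = Parameter(_he_normal(rng, (cout, cin // groups, k, k), fan_in))
        self.bias = Parameter(np.zeros(cout, dtype=_FLOAT), no_decay=True) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.pad, self.groups)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_he_normal(rng, (cin, cout), cin))
        self.bias = Parameter(np.zeros(cout, dtype=_FLOAT), no_decay=True)

    def forward(self, x):
        return add(matmul(x, self.weight), self.bias)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel with running stats.

    With batch size 1 the train-mode statistics are per-image; eps is kept
    relatively large for stability on small spatial maps.
    """

    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(c, dtype=_FLOAT), no_decay=True)
        self.beta = Parameter(np.zeros(c, dtype=_FLOAT), no_decay=True)
        self.running_mean = np.zeros(c, dtype=_FLOAT)
        self.running_var = np.ones(c, dtype=_FLOAT)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = tmean(x, axis=(0, 2, 3), keepdims=True)
            centered = x - mean
            var = tmean(mul(centered, centered), axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (
                mean.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (
                var.data.reshape(-1) - self.running_var)
            xhat = centered * power(var + self.eps, -0.5)
        else:
            mean = self.running_mean.reshape(1, -1, 1, 1)
            var = self.running_var.reshape(1, -1, 1, 1)
            xhat = (x - Tensor(mean)) * Tensor((var + self.eps) ** -0.5)
        g = reshape(self.gamma, (1, -1, 1, 1))
        b = reshape(self.beta, (1, -1, 1, 1))
        return xhat * g + b


class GroupNorm(Module):
    def __init__(self, groups: int, c: int, eps: float = 1e-5):
        super().__init__()
        if c % groups != 0:
            raise ValueError(f"channels {c} not divisible by {groups} groups")
        self.groups, self.eps = groups, eps
        self.gamma = Parameter(np.ones(c, dtype=_FLOAT), no_decay=True)
        self.beta = Parameter(np.zeros(c, dtype=_FLOAT), no_decay=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.groups
        xg = reshape(x, (n, g, c // g * h * w))
        mean = tmean(xg, axis=2, keepdims=True)
        centered = xg - mean
        var = tmean(mul(centered, centered), axis=2, keepdims=True)
        xhat = centered * power(var + self.eps, -0.5)
        xhat = reshape(xhat, (n, c, h, w))
        gm = reshape(self.gamma, (1, -1, 1, 1))
        bt = reshape(self.beta, (1, -1, 1, 1))
        return xhat * gm + bt


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C)."""
    return reshape(tmean(x, axis=(2, 3)), (x.shape[0], x.shape[1]))


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class AdamW:
    """AdamW with decoupled weight decay; `no_decay` parameters are exempt."""

    def __init__(self, params: Sequence[Parameter], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            mhat = m / bc1
            vhat = v / bc2
            if self.weight_decay and not getattr(p, "no_decay", False):
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
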