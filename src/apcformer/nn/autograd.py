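"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it;
``Tensor.backward()`` walks the tape in reverse topological order and
accumulates gradients into ``.grad``.  Only the operations the decoder needs
are implemented, each with an explicit vector-Jacobian product.  Broadcasting
follows NumPy semantics; gradients of broadcast operands are summed back to
the operand's shape.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` over axes that were broadcast from ``shape``."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data: Array | float,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[Array], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in _parents
        )
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward

    # -- plumbing --------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> Array:
        return self.data

    def _accumulate(self, grad: Array) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=grad.dtype)
        self.grad += grad

    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (layers x ops)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = _coerce(other, self.data.dtype)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _coerce(other, self.data.dtype)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_coerce(other, self.data.dtype))

    def __rsub__(self, other):
        return _coerce(other, self.data.dtype) + (-self)

    def __truediv__(self, other):
        other = _coerce(other, self.data.dtype)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return _coerce(other, self.data.dtype) * self ** (-1.0)

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, _parents=(self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = _coerce(other, self.data.dtype)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = bwd
        return out

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out = Tensor(self.data.reshape(shape), _parents=(self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        out._backward = bwd
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = bwd
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], _parents=(self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)

        out._backward = bwd
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _parents=(self,))

        def bwd(g: Array) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        idx = np.argmax(self.data, axis=axis)
        val = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis)
        out_data = val if keepdims else val.squeeze(axis)
        out = Tensor(out_data, _parents=(self,))

        def bwd(g: Array) -> None:
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis)
            self._accumulate(full)

        out._backward = bwd
        return out

    # -- elementwise nonlinearities -------------------------------------
    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, _parents=(self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * y)

        out._backward = bwd
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _parents=(self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bwd
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, _parents=(self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * y * (1.0 - y))

        out._backward = bwd
        return out

    def elu(self, alpha: float = 1.0) -> "Tensor":
        pos = self.data > 0
        y = np.where(pos, self.data, alpha * np.expm1(self.data))
        out = Tensor(y, _parents=(self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * np.where(pos, 1.0, y + alpha))

        out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _coerce(x, dtype) -> Tensor:
    """Wrap ``x`` as a Tensor; python scalars adopt ``dtype`` so mixing a
    float32 tensor with a literal does not promote to float64."""
    if isinstance(x, Tensor):
        return x
    if isinstance(x, (int, float)):
        return Tensor(np.asarray(x, dtype=dtype))
    return Tensor(x)


# -- free functions ------------------------------------------------------

def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g: Array) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    y = ez / ez.sum(axis=axis, keepdims=True)
    out = Tensor(y, _parents=(x,))

    def bwd(g: Array) -> None:
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (g - dot))

    out._backward = bwd
    return out


def where_const(cond: Array, x: Tensor, const: float) -> Tensor:
    """``cond ? x : const`` with gradient flowing through ``x`` only."""
    out = Tensor(np.where(cond, x.data, const), _parents=(x,))

    def bwd(g: Array) -> None:
        if x.requires_grad:
            x._accumulate(np.where(cond, g, 0.0))

    out._backward = bwd
    return out


def index_select(x: Tensor, idx: Array, axis: int) -> Tensor:
    """Gather along ``axis`` with one shared 1-D index array."""
    idx = np.asarray(idx)
    out = Tensor(np.take(x.data, idx, axis=axis), _parents=(x,))

    def bwd(g: Array) -> None:
        if x.requires_grad:
            full = np.zeros_like(x.data)
            sl: list = [slice(None)] * x.ndim
            sl[axis] = idx
            np.add.at(full, tuple(sl), g)
            x._accumulate(full)

    out._backward = bwd
    return out


def gather_tokens(x: Tensor, idx: Array) -> Tensor:
    """Per-batch gather of token rows.

    ``x``: (..., n, d); ``idx``: integer array (..., S) whose leading dims
    equal x's leading dims.  Returns (..., S, d) with
    ``out[..., s, :] = x[..., idx[..., s], :]``.
    """
    idx = np.asarray(idx)
    lead = x.shape[:-2]
    n, d = x.shape[-2:]
    if idx.shape[: len(lead)] != lead:
        raise ValueError(
            f"index leading dims {idx.shape[:len(lead)]} != tensor {lead}"
        )
    sel_shape = idx.shape[len(lead):]
    L = int(np.prod(lead)) if lead else 1
    S = int(np.prod(sel_shape)) if sel_shape else 1
    x2 = x.data.reshape(L, n, d)
    idx2 = idx.reshape(L, S)
    gathered = np.take_along_axis(x2, idx2[:, :, None], axis=1)
    out = Tensor(gathered.reshape(lead + sel_shape + (d,)), _parents=(x,))

    def bwd(g: Array) -> None:
        if x.requires_grad:
            g2 = g.reshape(L, S, d)
            full = np.zeros_like(x2)
            np.add.at(full, (np.arange(L)[:, None], idx2), g2)
            x._accumulate(full.reshape(x.shape))

    out._backward = bwd
    return out


# -- convolution / pooling primitives ------------------------------------

def _corr2d_raw(x: Array, w: Array, groups: int) -> Array:
    """Grouped cross-correlation, stride 1, no padding (raw arrays).

    x: (B, Cin, H, W); w: (Cout, Cin/groups, kh, kw) -> (B, Cout, Ho, Wo).
    """
    B, Cin, H, W = x.shape
    Cout, cg, kh, kw = w.shape
    og = Cout // groups
    xg = x.reshape(B, groups, cg, H, W)
    win = np.lib.stride_tricks.sliding_window_view(xg, (kh, kw), axis=(3, 4))
    # win: (B, G, cg, Ho, Wo, kh, kw)
    wg = w.reshape(groups, og, cg, kh, kw)
    out = np.einsum("bgcijuv,gocuv->bgoij", win, wg, optimize=True)
    return out.reshape(B, Cout, H - kh + 1, W - kw + 1)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           padding: tuple[int, int] = (0, 0), groups: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), stride 1, symmetric zero padding."""
    ph, pw = padding
    Cout, cg, kh, kw = weight.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    y = _corr2d_raw(xp, weight.data, groups)
    if bias is not None:
        y = y + bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y, _parents=parents)
    B, Cin, H, W = x.shape
    og = Cout // groups

    def bwd(g: Array) -> None:
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            xg = xp.reshape(B, groups, cg, H + 2 * ph, W + 2 * pw)
            win = np.lib.stride_tricks.sliding_window_view(
                xg, (kh, kw), axis=(3, 4))
            gg = g.reshape(B, groups, og, g.shape[2], g.shape[3])
            gw = np.einsum("bgcijuv,bgoij->gocuv", win, gg, optimize=True)
            weight._accumulate(gw.reshape(weight.shape))
        if x.requires_grad:
            # full correlation of padded grad with flipped kernels
            gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
            wf = weight.data[:, :, ::-1, ::-1].reshape(groups, og, cg, kh, kw)
            # swap roles: output channels become input channels per group
            wt = wf.transpose(0, 2, 1, 3, 4).reshape(groups * cg, og, kh, kw)
            gx_p = _corr2d_raw(gp, wt, groups)
            gx = gx_p[:, :, ph:ph + H, pw:pw + W] if (ph or pw) else gx_p
            x._accumulate(np.ascontiguousarray(gx))

    out._backward = bwd
    return out


def avg_pool2d(x: Tensor, kernel: tuple[int, int]) -> Tensor:
    """Average pooling with stride == kernel; trailing remainder dropped."""
    kh, kw = kernel
    B, C, H, W = x.shape
    Ho, Wo = H // kh, W // kw
    if Ho < 1 or Wo < 1:
        raise ValueError(f"pool kernel {kernel} larger than input {(H, W)}")
    core = x.data[:, :, :Ho * kh, :Wo * kw]
    y = core.reshape(B, C, Ho, kh, Wo, kw).mean(axis=(3, 5))
    out = Tensor(y, _parents=(x,))

    def bwd(g: Array) -> None:
        if x.requires_grad:
            full = np.zeros_like(x.data)
            g_exp = np.broadcast_to(
                g[:, :, :, None, :, None], (B, C, Ho, kh, Wo, kw)
            ) / (kh * kw)
            full[:, :, :Ho * kh, :Wo * kw] = g_exp.reshape(
                B, C, Ho * kh, Wo * kw)
            x._accumulate(full)

    out._backward = bwd
    return out
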