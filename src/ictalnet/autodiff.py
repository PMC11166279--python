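"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the substrate for the seizure-detection network: a ``Tensor`` wraps an
ndarray, records the operation that produced it, and ``backward()`` walks the
graph in reverse topological order accumulating gradients.  Only the
primitives the network needs are implemented (broadcast arithmetic, batched
matmul, grouped 2-D convolution, reductions, reshapes, GELU, exp/log/pow).
Everything else — softmax, layer/batch normalisation, attention — is composed
from these, so a single set of gradient checks covers the whole model.

All arrays are float64 throughout; the engine is small-scale by design
(CPU, minutes-long training runs) and favours correctness over speed.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from scipy.special import erf


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # reverse topological order
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def _needs_graph(self, *others: "Tensor") -> bool:
        return any(t.requires_grad or t._parents for t in (self, *others))

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], tuple]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(x, like: np.dtype | None = None) -> "Tensor":
        if isinstance(x, Tensor):
            return x
        arr = np.asarray(x)
        # keep scalar constants from promoting float32 tensors to float64
        if like is not None and arr.ndim == 0:
            arr = arr.astype(like)
        return Tensor(arr)

    def __add__(self, other):
        other = Tensor._coerce(other, self.data.dtype)
        return Tensor._make(
            self.data + other.data, (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._coerce(other, self.data.dtype))

    def __rsub__(self, other):
        return Tensor._coerce(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other, self.data.dtype)
        return Tensor._make(
            self.data * other.data, (self, other),
            lambda g: (_unbroadcast(g * other.data, self.shape),
                       _unbroadcast(g * self.data, other.shape)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other, self.data.dtype)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._coerce(other, self.data.dtype) * self ** -1.0

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        data = self.data ** exponent
        return Tensor._make(
            data, (self,),
            lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    def __matmul__(self, other):
        other = Tensor._coerce(other, self.data.dtype)
        data = np.matmul(self.data, other.data)

        def backward(g: np.ndarray):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor._make(data, (self, other), backward)

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        data = np.exp(self.data)
        return Tensor._make(data, (self,), lambda g: (g * data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def gelu(self):
        """Exact GELU, x * Phi(x) with the Gaussian CDF."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        data = x * phi
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        return Tensor._make(data, (self,), lambda g: (g * (phi + x * pdf),))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def maximum(self, other):
        """Elementwise max; ties send the gradient to ``self``."""
        other = Tensor._coerce(other, self.data.dtype)
        choose_self = self.data >= other.data
        data = np.where(choose_self, self.data, other.data)
        return Tensor._make(
            data, (self, other),
            lambda g: (_unbroadcast(g * choose_self, self.shape),
                       _unbroadcast(g * ~choose_self, other.shape)),
        )

    # -- reductions and shape ops -----------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: np.ndarray):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._make(
            self.data.reshape(shape), (self,),
            lambda g: (g.reshape(self.shape),),
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,),
            lambda g: (g.transpose(inv),),
        )

    # -- composed ops ------------------------------------------------------

    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"


# -- 2-D convolution -------------------------------------------------------

def same_padding(size: int, kernel: int, stride: int) -> tuple[int, int]:
    """Asymmetric 'same' padding with ceil output semantics.

    Output extent is ceil(size / stride); when total padding is odd the extra
    element goes after (TensorFlow convention).
    """
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    before = total // 2
    return before, total - before


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: str | tuple = "same",
           groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation over NCHW input.

    ``weight`` has shape (C_out, C_in // groups, kh, kw).  ``padding`` is
    either ``"same"`` (ceil semantics, see :func:`same_padding`), ``"valid"``
    or an explicit ((top, bottom), (left, right)) pair.  Depthwise convolution
    is ``groups == C_in`` with one weight slice per channel.
    """
    x = Tensor._coerce(x)
    B, C, H, W = x.shape
    Cout, Cg, kh, kw = weight.shape
    if C % groups or Cout % groups or Cg != C // groups:
        raise ValueError(f"incompatible channels {C}, groups {groups}, weight {weight.shape}")
    if padding == "same":
        ph, pw = same_padding(H, kh, stride), same_padding(W, kw, stride)
    elif padding == "valid":
        ph = pw = (0, 0)
    else:
        ph, pw = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), ph, pw))
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(f"input {H}x{W} smaller than kernel {kh}x{kw}")
    Cg_all, Cog = C // groups, Cout // groups
    # im2col by kernel-offset slices: (B, C, kh, kw, Ho, Wo) contiguous
    cols6 = np.empty((B, C, kh, kw, Ho, Wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols6[:, :, i, j] = xp[:, :, i:i + stride * Ho:stride,
                                   j:j + stride * Wo:stride]
    cols = cols6.reshape(B, groups, Cg_all * kh * kw, Ho * Wo)
    wg = weight.data.reshape(groups, Cog, Cg_all * kh * kw)
    out = np.matmul(wg, cols)                       # (B, groups, Cog, Ho*Wo)
    out = out.reshape(B, Cout, Ho, Wo)
    if bias is not None:
        out = out + bias.data.reshape(1, Cout, 1, 1)

    def backward(g: np.ndarray):
        gg = np.ascontiguousarray(g).reshape(B, groups, Cog, Ho * Wo)
        grad_w = None
        if weight.requires_grad or weight._parents:
            grad_w = np.matmul(gg, cols.swapaxes(-1, -2)).sum(axis=0)
            grad_w = grad_w.reshape(weight.shape)
        grad_x = None
        if x.requires_grad or x._parents:
            gcols = np.matmul(wg.swapaxes(-1, -2), gg)  # (B, groups, Cg*kh*kw, P)
            gcols = gcols.reshape(B, C, kh, kw, Ho, Wo)
            gxp = np.zeros((B, C, Hp, Wp), dtype=xp.dtype)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + stride * Ho:stride,
                        j:j + stride * Wo:stride] += gcols[:, :, i, j]
            grad_x = gxp[:, :, ph[0]:Hp - ph[1] or None, pw[0]:Wp - pw[1] or None]
        grad_b = None
        if bias is not None and (bias.requires_grad or bias._parents):
            grad_b = g.sum(axis=(0, 2, 3)).reshape(bias.shape)
        if bias is None:
            return grad_x, grad_w
        return grad_x, grad_w, grad_b

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out, parents, backward)
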