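"""Reverse-mode automatic differentiation over numpy arrays.

A small tensor engine sufficient for training convolutional detectors on a
CPU: broadcasting arithmetic, matmul, reductions, 2-D convolution (im2col),
bilinear gathers at fractional coordinates (the primitive behind deformable
sampling), and an SGD optimizer with momentum.  Everything is float64, which
keeps finite-difference gradient checks tight.

Conventions
-----------
* Image tensors are laid out ``(B, C, H, W)``; single feature maps ``(C, H, W)``.
* ``Tensor.detach()`` returns a value that participates in the forward pass
  but receives no gradient — used for the "starred" (non-backpropagated)
  quantities of the Wise-IOU loss.
* Reductions with ties (``max``) split the gradient uniformly among the tied
  elements.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "bilinear_gather",
    "upsample2x",
    "bce_with_logits",
    "SGD",
]


class Tensor:
    """A numpy array plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------ meta
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        return _binary(self, other, np.add,
                       lambda g, a, b: (g, g))

    __radd__ = __add__

    def __neg__(self):
        return _unary(self, np.negative, lambda g, x: -g)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, np.divide,
                       lambda g, a, b: (g / b, -g * a / (b * b)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def bwd(g, x):
            return g * e * np.power(x, e - 1.0)

        return _unary(self, lambda x: np.power(x, e), bwd)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bwd(g):
            return g @ other.data.T, self.data.T @ g

        return _from_op(self.data @ other.data, (self, other), bwd)

    # ------------------------------------------------------------- unary fns
    def exp(self):
        out = np.exp(self.data)
        return _from_op(out, (self,), lambda g: (g * out,))

    def log(self):
        return _unary(self, np.log, lambda g, x: g / x)

    def sqrt(self):
        out = np.sqrt(self.data)
        return _from_op(out, (self,), lambda g: (g / (2.0 * out),))

    def sigmoid(self):
        out = _sigmoid(self.data)
        return _from_op(out, (self,), lambda g: (g * out * (1.0 - out),))

    def relu(self):
        mask = self.data > 0
        return _from_op(self.data * mask, (self,), lambda g: (g * mask,))

    def silu(self):
        s = _sigmoid(self.data)
        out = self.data * s
        return _from_op(out, (self,),
                        lambda g: (g * (s + out * (1.0 - s)),))

    def arctan(self):
        return _unary(self, np.arctan, lambda g, x: g / (1.0 + x * x))

    def clip(self, lo, hi):
        mask = (self.data >= lo) & (self.data <= hi)
        return _from_op(np.clip(self.data, lo, hi), (self,),
                        lambda g: (g * mask,))

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return _from_op(out, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims=False):
        out = self.data.max(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            ref = out
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
                ref = np.expand_dims(out, axis)
            mask = (self.data == ref)
            count = mask.sum(axis=axis, keepdims=True)
            return (mask * (g / count),)

        return _from_op(out, (self,), bwd)

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return _from_op(self.data.reshape(shape), (self,),
                        lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return _from_op(self.data.transpose(axes), (self,),
                        lambda g: (g.transpose(inv),))

    def __getitem__(self, key):
        out = self.data[key]

        def bwd(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, key, g)
            return (gx,)

        return _from_op(out, (self,), bwd)

    # -------------------------------------------------------------- backward
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
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
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not (p.requires_grad or p._parents):
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


# --------------------------------------------------------------------- utils

def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _from_op(data, parents, backward) -> Tensor:
    t = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        t._parents = tuple(parents)
        t._backward = backward
    return t


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient back down to ``shape`` after numpy broadcasting."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _binary(a, b, fwd, bwd):
    a, b = as_tensor(a), as_tensor(b)
    out = fwd(a.data, b.data)

    def backward(g):
        ga, gb = bwd(g, a.data, b.data)
        return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

    return _from_op(out, (a, b), backward)


def _unary(x, fwd, bwd):
    x = as_tensor(x)
    return _from_op(fwd(x.data), (x,), lambda g: (bwd(g, x.data),))


def maximum(a, b) -> Tensor:
    """Elementwise maximum; ties route the gradient to the first argument."""
    a, b = as_tensor(a), as_tensor(b)
    take_a = a.data >= b.data
    out = np.where(take_a, a.data, b.data)

    def bwd(g):
        return (_unbroadcast(g * take_a, a.data.shape),
                _unbroadcast(g * ~take_a, b.data.shape))

    return _from_op(out, (a, b), bwd)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return _from_op(out, tuple(tensors), bwd)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        return tuple(np.moveaxis(g, axis, 0))

    return _from_op(out, tuple(tensors), bwd)


# ----------------------------------------------------------------- conv2d op

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    """View a padded (B,C,Hp,Wp) array as (B,Ho,Wo,C,kh,kw) patches."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]          # (B,C,Ho,Wo,kh,kw)
    return win.transpose(0, 2, 3, 1, 4, 5)       # (B,Ho,Wo,C,kh,kw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation of (B,C,H,W) with (O,C,kh,kw), zero padding."""
    x, w = as_tensor(x), as_tensor(w)
    B, C, H, W = x.data.shape
    O, Cw, kh, kw = w.data.shape
    if C != Cw:
        raise ValueError(f"channel mismatch: input {C} vs kernel {Cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = _im2col(xp, kh, kw, stride)           # (B,Ho,Wo,C,kh,kw)
    Ho, Wo = cols.shape[1], cols.shape[2]
    cols2 = np.ascontiguousarray(cols).reshape(B * Ho * Wo, C * kh * kw)
    wflat = w.data.reshape(O, -1)
    out = (cols2 @ wflat.T).reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)

    def bwd(g):
        gout = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, O)
        gw = (gout.T @ cols2).reshape(w.data.shape)
        gcols = (gout @ wflat).reshape(B, Ho, Wo, C, kh, kw)
        gxp = np.zeros_like(xp)
        for ky in range(kh):
            for kx in range(kw):
                gxp[:, :, ky:ky + stride * Ho:stride,
                    kx:kx + stride * Wo:stride] += \
                    gcols[:, :, :, :, ky, kx].transpose(0, 3, 1, 2)
        gx = gxp[:, :, padding:padding + H, padding:padding + W] \
            if padding else gxp
        return gx, gw

    out_t = _from_op(out, (x, w), bwd)
    if b is not None:
        out_t = out_t + as_tensor(b).reshape(1, -1, 1, 1)
    return out_t


# ------------------------------------------------------- bilinear gather op

def bilinear_gather(x: Tensor, ys: Tensor, xs: Tensor) -> Tensor:
    """Sample (B,C,H,W) at fractional coordinates, zero outside the map.

    ``ys``/``xs`` have shape (B,K,Ho,Wo); the result is (B,C,K,Ho,Wo).
    The value at a point is the bilinear combination of its four integer
    neighbours (the separable triangular kernel); positions outside the map
    contribute zero.  Gradients flow to the map and to the coordinates.
    """
    x, ys, xs = as_tensor(x), as_tensor(ys), as_tensor(xs)
    B, C, H, W = x.data.shape
    yd, xd = ys.data, xs.data
    y0 = np.floor(yd)
    x0 = np.floor(xd)
    fy = yd - y0        # weight of the y0+1 row
    fx = xd - x0
    xflat = x.data.reshape(B, C, H * W)

    corners = []        # (value(B,C,K,Ho,Wo), weight, dw/dy, dw/dx, idx, valid)
    for dy, wy, dwy in ((0, 1.0 - fy, -1.0), (1, fy, 1.0)):
        with np.errstate(invalid="ignore"):  # non-finite coords resolve to invalid
            yi = (y0 + dy).astype(np.int64)
        vy = (yi >= 0) & (yi < H)
        yi_c = np.clip(yi, 0, H - 1)
        for dx, wx, dwx in ((0, 1.0 - fx, -1.0), (1, fx, 1.0)):
            with np.errstate(invalid="ignore"):
                xi = (x0 + dx).astype(np.int64)
            valid = vy & (xi >= 0) & (xi < W)
            idx = yi_c * W + np.clip(xi, 0, W - 1)
            flat = idx.reshape(B, 1, -1)
            v = np.take_along_axis(xflat, np.broadcast_to(flat, (B, C, flat.shape[-1])), axis=2)
            v = v.reshape(B, C, *yd.shape[1:]) * valid[:, None]
            corners.append((v, wy * wx, dwy * wx, wy * dwx, idx, valid))

    out = sum(v * w[:, None] for v, w, _, _, _, _ in corners)

    def bwd(g):
        gx = np.zeros((B, C, H * W))
        gy = np.zeros_like(yd)
        gxc = np.zeros_like(xd)
        bidx = np.arange(B).reshape(B, 1, 1, 1, 1)
        cidx = np.arange(C).reshape(1, C, 1, 1, 1)
        for v, w, dwy, dwx, idx, valid in corners:
            gv = g * (w * valid)[:, None]
            np.add.at(gx, (bidx, cidx, idx[:, None]), gv)
            gs = (g * v).sum(axis=1)           # (B,K,Ho,Wo)
            gy += gs * dwy * valid
            gxc += gs * dwx * valid
        return gx.reshape(B, C, H, W), gy, gxc

    return _from_op(out, (x, ys, xs), bwd)


# --------------------------------------------------------------- other ops

def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling of (B,C,H,W)."""
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bwd(g):
        return (g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)),)

    return _from_op(out, (x,), bwd)


def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    weights: np.ndarray | None = None) -> Tensor:
    """Numerically stable binary cross-entropy; returns the (weighted) mean."""
    z = as_tensor(logits)
    y = np.asarray(targets, dtype=np.float64)
    zd = z.data
    loss = np.maximum(zd, 0.0) - zd * y + np.log1p(np.exp(-np.abs(zd)))
    if weights is None:
        w = np.full(zd.shape, 1.0 / zd.size)
    else:
        w = np.asarray(weights, dtype=np.float64)
        w = w / w.sum()
    out = float((loss * w).sum())

    def bwd(g):
        return (g * w * (_sigmoid(zd) - y),)

    return _from_op(out, (z,), bwd)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.9):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v
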