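"""Deformable 2-D convolution and deformable ROI pooling.

A deformable convolution displaces each of the K = N*N kernel sampling points
by a learned per-location offset and resolves the resulting fractional
positions with bilinear interpolation (the separable triangular kernel
``g(a,b) = max(0, 1 - |a-b|)``).  With all offsets zero it reduces exactly to
a standard convolution, which is the main correctness oracle used in the
tests.

Layout and coordinate conventions
---------------------------------
* Feature maps are ``(C, H, W)`` (or ``(B, C, H, W)`` for the batched ops),
  indexed ``(row, col) = (y, x)``, 0-based, pixel centers at integer
  coordinates.  Positions outside the map contribute zero (zero padding).
* Offset fields have ``2K`` channels ordered k-major as ``(dy_k, dx_k)``
  pairs, with k enumerating the kernel grid row-major.
* ROIs are half-open pixel rectangles ``[x1, x2) x [y1, y2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, bilinear_gather, conv2d

__all__ = [
    "RoiSpec",
    "bilinear_kernel_1d",
    "sample_bilinear",
    "kernel_grid",
    "standard_conv2d",
    "deform_conv2d",
    "deform_conv2d_t",
    "make_offset_branch",
    "OffsetBranch",
    "deform_roi_pool",
]


@dataclass
class RoiSpec:
    """A half-open ROI divided into t x t subregions, each with a (dy, dx) offset."""

    x1: float
    y1: float
    x2: float
    y2: float
    t: int
    subregion_offsets: np.ndarray = field(default=None)  # (t, t, 2) as (dy, dx)

    def __post_init__(self):
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise ValueError("ROI must have positive extent")
        if self.subregion_offsets is None:
            self.subregion_offsets = np.zeros((self.t, self.t, 2))
        self.subregion_offsets = np.asarray(self.subregion_offsets, dtype=np.float64)
        if self.subregion_offsets.shape != (self.t, self.t, 2):
            raise ValueError("subregion_offsets must have shape (t, t, 2)")


def bilinear_kernel_1d(a: float, b: float) -> float:
    """One-dimensional triangular interpolation kernel max(0, 1 - |a - b|)."""
    return max(0.0, 1.0 - abs(float(a) - float(b)))


def sample_bilinear(fm: np.ndarray, channel: int, p: tuple[float, float]) -> float:
    """Bilinearly interpolate one channel of a (C,H,W) map at point ``p`` = (y, x).

    The value is the sum over the (at most four) integer neighbours q of
    ``g(q_y, p_y) * g(q_x, p_x) * x(q)``; out-of-map neighbours contribute 0.
    """
    fm = np.asarray(fm, dtype=np.float64)
    _, H, W = fm.shape
    py, px = float(p[0]), float(p[1])
    y0, x0 = int(np.floor(py)), int(np.floor(px))
    total = 0.0
    for qy in (y0, y0 + 1):
        for qx in (x0, x0 + 1):
            if 0 <= qy < H and 0 <= qx < W:
                total += (bilinear_kernel_1d(qy, py) * bilinear_kernel_1d(qx, px)
                          * fm[channel, qy, qx])
    return total


def kernel_grid(n: int) -> np.ndarray:
    """The K = n*n predefined sampling positions p_k of an n x n kernel.

    Returned row-major as (dy, dx) relative to the kernel's top-left corner,
    matching the sliding-window origin used by :func:`standard_conv2d`.
    """
    ys, xs = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return np.stack([ys.ravel(), xs.ravel()], axis=1).astype(np.float64)


def standard_conv2d(fm: np.ndarray, weights: np.ndarray,
                    stride: int = 1, padding: int = 0) -> np.ndarray:
    """Plain cross-correlation of a (C,H,W) map with (O,C,N,N) weights.

    This is the zero-offset oracle for :func:`deform_conv2d`; it uses integer
    indexing only (no interpolation).
    """
    fm = np.asarray(fm, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if fm.ndim != 3 or weights.ndim != 4:
        raise ValueError("expected (C,H,W) input and (O,C,kh,kw) weights")
    if fm.shape[0] != weights.shape[1]:
        raise ValueError(
            f"channel mismatch: input {fm.shape[0]} vs kernel {weights.shape[1]}")
    out = conv2d(Tensor(fm[None]), Tensor(weights), stride=stride, padding=padding)
    return out.data[0]


def _deform_positions(K: int, n: int, H_out: int, W_out: int,
                      stride: int, padding: int):
    """Base sampling coordinates p_0 + p_k for every output cell, (K,Ho,Wo)."""
    grid = kernel_grid(n)                                # (K,2)
    oy = np.arange(H_out) * stride - padding
    ox = np.arange(W_out) * stride - padding
    base_y = grid[:, 0][:, None, None] + oy[None, :, None]
    base_x = grid[:, 1][:, None, None] + ox[None, None, :]
    return (np.broadcast_to(base_y, (K, H_out, W_out)).copy(),
            np.broadcast_to(base_x, (K, H_out, W_out)).copy())


def deform_conv2d_t(fm: Tensor, weights: Tensor, offsets: Tensor,
                    stride: int = 1, padding: int = 0,
                    modulation: Tensor | None = None) -> Tensor:
    """Differentiable deformable convolution on batched tensors.

    ``fm`` is (B,C,H,W); ``weights`` (O,C,N,N); ``offsets`` (B,2K,Ho,Wo) with
    k-major (dy_k, dx_k) channel pairs.  Optional ``modulation`` (B,K,Ho,Wo)
    multiplies each sampled value by a sigmoid gate.
    """
    fm, weights, offsets = as_tensor(fm), as_tensor(weights), as_tensor(offsets)
    B, C, H, W = fm.shape
    O, Cw, n, n2 = weights.shape
    if n != n2:
        raise ValueError("kernel must be square")
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C} vs kernel {Cw}")
    K = n * n
    H_out = (H + 2 * padding - n) // stride + 1
    W_out = (W + 2 * padding - n) // stride + 1
    if offsets.shape != (B, 2 * K, H_out, W_out):
        raise ValueError(
            f"offset field must have shape {(B, 2 * K, H_out, W_out)}, "
            f"got {offsets.shape}")
    base_y, base_x = _deform_positions(K, n, H_out, W_out, stride, padding)
    ys = offsets[:, 0::2] + base_y[None]
    xs = offsets[:, 1::2] + base_x[None]
    sampled = bilinear_gather(fm, ys, xs)                # (B,C,K,Ho,Wo)
    if modulation is not None:
        sampled = sampled * as_tensor(modulation).sigmoid().reshape(
            B, 1, K, H_out, W_out)
    cols = sampled.reshape(B, C * K, H_out * W_out)
    wflat = weights.reshape(O, C * K)
    # contract (O, C*K) with (B, C*K, L) by flattening the batch into columns
    cols2 = cols.transpose(1, 0, 2).reshape(C * K, B * H_out * W_out)
    out = (wflat @ cols2).reshape(O, B, H_out * W_out).transpose(1, 0, 2)
    return out.reshape(B, O, H_out, W_out)


def deform_conv2d(fm: np.ndarray, weights: np.ndarray, offsets: np.ndarray,
                  stride: int = 1, padding: int = 0,
                  modulation: np.ndarray | None = None) -> np.ndarray:
    """Deformable convolution of a single (C,H,W) map (numpy in, numpy out).

    Each kernel sampling point p_k is displaced by its offset (dy_k, dx_k)
    before the weighted sum; fractional positions are bilinearly interpolated
    and out-of-map samples read as zero.  With zero offsets this equals
    :func:`standard_conv2d`.
    """
    out = deform_conv2d_t(
        Tensor(np.asarray(fm, dtype=np.float64)[None]),
        Tensor(weights),
        Tensor(np.asarray(offsets, dtype=np.float64)[None]),
        stride=stride, padding=padding,
        modulation=None if modulation is None
        else Tensor(np.asarray(modulation, dtype=np.float64)[None]))
    return out.data[0]


class OffsetBranch:
    """A 3x3 convolution producing a 2K-channel offset field.

    Weights and bias initialize to zero, so a freshly built deformable layer
    behaves exactly like a standard convolution until training moves the
    offsets.
    """

    def __init__(self, in_channels: int, K: int, extra_channels: int = 0):
        self.K = K
        out_ch = 2 * K + extra_channels
        self.weight = Tensor(np.zeros((out_ch, in_channels, 3, 3)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, fm: Tensor) -> Tensor:
        fm = as_tensor(fm)
        x = fm if fm.ndim == 4 else fm.reshape(1, *fm.shape)
        out = conv2d(x, self.weight, self.bias, stride=1, padding=1)
        return out if fm.ndim == 4 else out.reshape(*out.shape[1:])

    def parameters(self):
        return [self.weight, self.bias]


def make_offset_branch(in_channels: int, K: int) -> OffsetBranch:
    """Build the learned offset-generation pathway (zero-initialized)."""
    return OffsetBranch(in_channels, K)


def deform_roi_pool(fm: np.ndarray, roi: RoiSpec, n_samples: int = 2) -> np.ndarray:
    """Deformable ROI max pooling: (C,H,W) -> (C, t, t).

    The ROI is divided into t x t half-open subregions; each subregion is
    translated by its (dy, dx) offset, sampled on an ``n_samples`` x
    ``n_samples`` interior grid via bilinear interpolation, max-reduced, and
    the results are assembled row-major.

    The interior sample grid places points at ``edge - 0.5 + (s + 0.5) * side
    / n`` so that a subregion of side ``n_samples`` pixels with zero offset is
    sampled exactly at its integer pixel centers — plain max pooling.
    """
    fm = np.asarray(fm, dtype=np.float64)
    if fm.ndim != 3:
        raise ValueError("expected a (C,H,W) feature map")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    C = fm.shape[0]
    t = roi.t
    bin_w = (roi.x2 - roi.x1) / t
    bin_h = (roi.y2 - roi.y1) / t
    out = np.empty((C, t, t))
    rel = (np.arange(n_samples) + 0.5) / n_samples
    for ti in range(t):
        for tj in range(t):
            dy, dx = roi.subregion_offsets[ti, tj]
            ys = roi.y1 - 0.5 + (ti + rel) * bin_h + dy
            xs = roi.x1 - 0.5 + (tj + rel) * bin_w + dx
            for c in range(C):
                out[c, ti, tj] = max(
                    sample_bilinear(fm, c, (y, x)) for y in ys for x in xs)
    return out
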