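"""Layers for the detector, built on :mod:`aquadet.autodiff`.

Contains the module/parameter plumbing (named state dict, train/eval mode)
plus the building blocks the detector assembles: convolution + batch norm +
SiLU blocks, cross-stage C2f blocks and their deformable variant, channel
attention, and nearest-neighbour upsampling.
"""

from __future__ import annotations

import numpy as np

from . import attention as attn
from .autodiff import Tensor, bilinear_gather, concat, conv2d
from .deformable import OffsetBranch, _deform_positions, deform_conv2d_t

__all__ = [
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ConvBlock",
    "DeformConvBlock",
    "DeformMaxPool",
    "Bottleneck",
    "C2f",
    "ChannelAttention",
]


class Module:
    """Base class: walks attributes to collect parameters and submodules."""

    training: bool = True

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, (Module, OffsetBranch)):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, (Module, OffsetBranch)):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield f"{prefix}{name}", value
        for name, child in self._children():
            if isinstance(child, OffsetBranch):
                yield f"{prefix}{name}.weight", child.weight
                yield f"{prefix}{name}.bias", child.bias
            else:
                yield from child.named_parameters(f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters(prefix)}
        for name, buf in self._named_buffers(prefix).items():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True):
        own = dict(self.named_parameters())
        own.update(self._named_buffers())
        for key, val in state.items():
            if key not in own:
                if strict:
                    raise KeyError(f"unexpected key {key!r}")
                continue
            target = own[key]
            if isinstance(target, Tensor):
                target.data = np.array(val, dtype=np.float64)
            else:
                target[...] = val
        if strict:
            missing = set(own) - set(state)
            if missing:
                raise KeyError(f"missing keys: {sorted(missing)}")

    def _named_buffers(self, prefix: str = ""):
        out = {}
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                out[f"{prefix}{name}"] = value
        for name, child in self._children():
            if isinstance(child, Module):
                out.update(child._named_buffers(f"{prefix}{name}."))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            if isinstance(child, Module):
                child.train(mode)
        return self

    def eval(self):
        return self.train(False)


def _kaiming(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 padding: int | None = None, bias: bool = True, *,
                 rng: np.random.Generator):
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.weight = Tensor(_kaiming(rng, (c_out, c_in, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    """Per-channel normalization; batch statistics while training, running
    statistics in eval mode."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean += m * (mu.data.ravel() - self.running_mean)
            self.running_var += m * (var.data.ravel() - self.running_var)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xn = (x - mu) * ((var + self.eps) ** -0.5)
        return xn * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class ConvBlock(Module):
    """Conv -> BatchNorm -> SiLU."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1, *,
                 rng: np.random.Generator):
        self.conv = Conv2d(c_in, c_out, k, stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(c_out)

    def __call__(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).silu()


class DeformConvBlock(Module):
    """Deformable conv (zero-initialized offset branch) -> BatchNorm -> SiLU.

    Optionally modulated: the offset branch then emits K extra channels used
    as sigmoid gates on the sampled values.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1, *,
                 modulated: bool = False, rng: np.random.Generator):
        self.k = k
        self.stride = stride
        self.modulated = modulated
        K = k * k
        self.weight = Tensor(_kaiming(rng, (c_out, c_in, k, k)), requires_grad=True)
        self.offset_branch = OffsetBranch(c_in, K, extra_channels=K if modulated else 0)
        self.bn = BatchNorm2d(c_out)

    def __call__(self, x: Tensor) -> Tensor:
        K = self.k * self.k
        raw = self.offset_branch(x)
        if self.stride != 1:
            raw = raw[:, :, ::self.stride, ::self.stride]
        offsets = raw[:, :2 * K]
        mod = raw[:, 2 * K:] if self.modulated else None
        out = deform_conv2d_t(x, self.weight, offsets,
                              stride=self.stride, padding=self.k // 2,
                              modulation=mod)
        return self.bn(out).silu()


class DeformMaxPool(Module):
    """Resolution-preserving deformable pooling stage.

    The full map is treated as one ROI with 1x1-pixel subregions; a 3x3 conv
    (zero-initialized) predicts one (dy, dx) offset per location and each
    output value is the map sampled at its displaced pixel center.  With zero
    offsets this is exactly the identity, so inserting the stage does not
    perturb a freshly initialized network.
    """

    def __init__(self, c_in: int, *, rng: np.random.Generator):
        self.offset_branch = OffsetBranch(c_in, 1)

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        off = self.offset_branch(x)                       # (B,2,H,W)
        base_y, base_x = _deform_positions(1, 1, H, W, 1, 0)
        ys = off[:, 0:1] + base_y[None]
        xs = off[:, 1:2] + base_x[None]
        sampled = bilinear_gather(x, ys, xs)              # (B,C,1,H,W)
        return sampled.reshape(B, C, H, W)


class Bottleneck(Module):
    """Two 3x3 convolutions with a residual connection; optionally deformable."""

    def __init__(self, channels: int, deformable: bool = False, *,
                 rng: np.random.Generator):
        block = DeformConvBlock if deformable else ConvBlock
        self.cv1 = block(channels, channels, 3, rng=rng)
        self.cv2 = block(channels, channels, 3, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.cv2(self.cv1(x))


class C2f(Module):
    """Cross-stage block: split, run bottlenecks on one half, concatenate all.

    ``deformable=True`` makes both bottleneck convolutions deformable and
    appends a resolution-preserving deformable pooling stage.
    """

    def __init__(self, c_in: int, c_out: int, n: int = 1,
                 deformable: bool = False, roi_pool_stage: bool | None = None, *,
                 rng: np.random.Generator):
        self.half = c_out // 2
        self.cv1 = ConvBlock(c_in, 2 * self.half, 1, rng=rng)
        self.bottlenecks = [Bottleneck(self.half, deformable, rng=rng)
                            for _ in range(n)]
        self.cv2 = ConvBlock((2 + n) * self.half, c_out, 1, rng=rng)
        if roi_pool_stage is None:
            roi_pool_stage = deformable
        self.pool = DeformMaxPool(c_out, rng=rng) if roi_pool_stage else None

    def __call__(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        parts = [y[:, :self.half], y[:, self.half:]]
        for b in self.bottlenecks:
            parts.append(b(parts[-1]))
        out = self.cv2(concat(parts, axis=1))
        if self.pool is not None:
            out = self.pool(out)
        return out


class ChannelAttention(Module):
    """SE / DPSE channel recalibration layer (no biases in the bottleneck)."""

    def __init__(self, channels: int, kind: str = "dpse", reduction: int = 16,
                 inner_sigmoid: bool = True, *, rng: np.random.Generator):
        if kind not in ("se", "dpse"):
            raise ValueError("kind must be 'se' or 'dpse'")
        self.kind = kind
        self.inner_sigmoid = inner_sigmoid
        mid = attn.bottleneck_width(channels, reduction)
        s1, s2 = 1.0 / np.sqrt(channels), 1.0 / np.sqrt(mid)
        self.W1 = Tensor(rng.uniform(-s1, s1, (mid, channels)), requires_grad=True)
        self.W2 = Tensor(rng.uniform(-s2, s2, (channels, mid)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        z = x.mean(axis=(2, 3))                           # (B,C)
        if self.kind == "dpse":
            z = z + x.max(axis=(2, 3))
            if self.inner_sigmoid:
                z = z.sigmoid()
        s = ((z @ self.W1.transpose(1, 0)).relu() @ self.W2.transpose(1, 0)).sigmoid()
        return x * s.reshape(B, C, 1, 1)
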