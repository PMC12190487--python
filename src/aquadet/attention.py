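"""Squeeze-and-excitation channel attention and its dual-pooling variant.

SE computes a per-channel descriptor by global average pooling (squeeze),
passes it through a two-layer bottleneck with ReLU and sigmoid (excite), and
rescales each channel by the resulting weight in (0,1).

The dual-pooling variant (DPSE) replaces the average-pool squeeze with the
sum of the spatial average and the spatial maximum — average pooling keeps
global context while max pooling highlights high-contrast local texture — and
inserts an extra sigmoid on the combined descriptor before the bottleneck.

The functions here are plain numpy (used directly and as oracles); the
detector uses the :class:`~aquadet.nn.ChannelAttention` layer, which shares
these formulas through the autodiff engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SqueezeExciteParams",
    "se_squeeze",
    "dpse_squeeze",
    "se_excite",
    "dpse_excite",
    "recalibrate",
    "bottleneck_width",
]


def bottleneck_width(channels: int, reduction: int, floor: int = 4) -> int:
    """Width of the excitation bottleneck: C / r, floored, never below ``floor``."""
    return max(min(floor, channels), channels // reduction)


@dataclass
class SqueezeExciteParams:
    """Weights of the two excitation layers (no biases: zero weights give 0.5)."""

    W1: np.ndarray  # (C/r, C)
    W2: np.ndarray  # (C, C/r)

    def __post_init__(self):
        self.W1 = np.asarray(self.W1, dtype=np.float64)
        self.W2 = np.asarray(self.W2, dtype=np.float64)
        if self.W1.ndim != 2 or self.W2.ndim != 2 or \
                self.W1.shape[0] != self.W2.shape[1] or \
                self.W1.shape[1] != self.W2.shape[0]:
            raise ValueError(
                f"incompatible excitation shapes {self.W1.shape} / {self.W2.shape}")

    @staticmethod
    def init(channels: int, reduction: int = 16, rng: np.random.Generator | None = None
             ) -> "SqueezeExciteParams":
        mid = bottleneck_width(channels, reduction)
        if rng is None:
            return SqueezeExciteParams(np.zeros((mid, channels)),
                                       np.zeros((channels, mid)))
        s1 = 1.0 / np.sqrt(channels)
        s2 = 1.0 / np.sqrt(mid)
        return SqueezeExciteParams(rng.uniform(-s1, s1, (mid, channels)),
                                   rng.uniform(-s2, s2, (channels, mid)))


def _check_map(fm: np.ndarray) -> np.ndarray:
    fm = np.asarray(fm, dtype=np.float64)
    if fm.ndim != 3 or 0 in fm.shape:
        raise ValueError("expected a non-empty (C,H,W) feature map")
    return fm


def se_squeeze(fm: np.ndarray) -> np.ndarray:
    """Per-channel spatial mean of a (C,H,W) map -> length-C descriptor."""
    return _check_map(fm).mean(axis=(1, 2))


def dpse_squeeze(fm: np.ndarray) -> np.ndarray:
    """Dual-pooling squeeze: per-channel spatial mean plus spatial max."""
    fm = _check_map(fm)
    return fm.mean(axis=(1, 2)) + fm.max(axis=(1, 2))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def se_excite(z: np.ndarray, p: SqueezeExciteParams) -> np.ndarray:
    """sigmoid(W2 @ relu(W1 @ z)) -> channel weights in (0,1)."""
    z = np.asarray(z, dtype=np.float64)
    if z.shape != (p.W1.shape[1],):
        raise ValueError(f"descriptor length {z.shape} incompatible with W1 {p.W1.shape}")
    return _sigmoid(p.W2 @ np.maximum(p.W1 @ z, 0.0))


def dpse_excite(z: np.ndarray, p: SqueezeExciteParams,
                inner_sigmoid: bool = True) -> np.ndarray:
    """sigmoid(W2 @ relu(W1 @ sigmoid(z))).

    The inner sigmoid bounds the combined avg+max descriptor to (0,1); set
    ``inner_sigmoid=False`` to ablate it.
    """
    z = np.asarray(z, dtype=np.float64)
    return se_excite(_sigmoid(z) if inner_sigmoid else z, p)


def recalibrate(fm: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Channel-wise rescaling: channel c of the output is s_c * channel c."""
    fm = _check_map(fm)
    s = np.asarray(s, dtype=np.float64)
    if s.shape != (fm.shape[0],):
        raise ValueError(f"{s.shape[0] if s.ndim else 0} weights for {fm.shape[0]} channels")
    return fm * s[:, None, None]
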