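import numpy as np
import pytest

from aquadet.boxes import BoundingBox


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_box(rng, span: float = 40.0) -> BoundingBox:
    return BoundingBox(cx=rng.uniform(-span, span), cy=rng.uniform(-span, span),
                       w=rng.uniform(0.5, span), h=rng.uniform(0.5, span))


def finite_difference(tensor, func, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of scalar ``func()`` w.r.t. ``tensor.data``."""
    grad = np.zeros_like(tensor.data)
    it = np.nditer(tensor.data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = tensor.data[i]
        tensor.data[i] = old + eps
        fp = func()
        tensor.data[i] = old - eps
        fm = func()
        tensor.data[i] = old
        grad[i] = (fp - fm) / (2 * eps)
    return grad
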