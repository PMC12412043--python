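import numpy as np
import pytest

from canet import SyntheticSpec, generate_synthetic
from canet import nn


@pytest.fixture(autouse=True)
def _seeded_init():
    """Deterministic weight initialisation for every test."""
    nn.manual_seed(0)
    yield


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def micro_dataset(tmp_path_factory):
    """16 tiny synthetic image/mask pairs on disk (32x32)."""
    root = tmp_path_factory.mktemp("micro")
    spec = SyntheticSpec(n_images=16, image_size=(32, 32), seed=11,
                         area_fraction=(0.02, 0.25))
    pairs = generate_synthetic(spec, root)
    return root, pairs


def numeric_grad(f, x: np.ndarray, eps: float = 1e-2) -> np.ndarray:
    """Central finite differences of a scalar function of the array `x`."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g
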