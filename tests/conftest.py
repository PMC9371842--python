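import numpy as np
import pytest

from maskdet.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_bundle():
    """A 20-image one-class dataset shared by IO/pipeline tests."""
    cfg = GeneratorConfig(width=64, height=64, n_classes=2,
                          lesions_per_image=(0, 3), noise_sigma=0.05)
    return generate_dataset(20, cfg, seed=11)


def numeric_gradient(f, x, eps=1e-5):
    """Central-difference gradient of scalar f at array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g
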