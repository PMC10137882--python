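import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def trimodal_histogram():
    """Histogram of Gaussian draws around modes 40/130/220 (sigma 8)."""
    from msar import normalized_histogram

    g = np.random.default_rng(42)
    vals = np.concatenate(
        [g.normal(40, 8, 2000), g.normal(130, 8, 3000), g.normal(220, 8, 5000)]
    )
    pixels = np.clip(np.round(vals), 0, 255).astype(np.uint8)
    return normalized_histogram(pixels)


@pytest.fixture(scope="session")
def cell_image():
    """Synthetic blood-smear-like RGB image with its ground truth."""
    from msar import CellImageSpec, generate_cell_image

    return generate_cell_image(CellImageSpec(seed=1))


def random_fuzzy_chain(g: np.random.Generator, n_triplets: int) -> np.ndarray:
    """Strictly increasing chain of 3*n values in [0, 255]."""
    while True:
        chain = np.sort(g.uniform(0.0, 255.0, 3 * n_triplets))
        if np.all(np.diff(chain) > 0):
            return chain.reshape(n_triplets, 3)
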