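import numpy as np
import pytest

from chipcyte import SceneParams, generate_field


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_scene(seed: int = 1, **kw) -> SceneParams:
    """A fast 256×256 scene for protocol-level tests."""
    defaults = dict(height=256, width=256, n_cells=6, gfp_fraction=0.5,
                    clump_probability=0.2, snr=10.0, post_height=20, rng_seed=seed)
    defaults.update(kw)
    return SceneParams(**defaults)


@pytest.fixture
def small_field():
    return generate_field(small_scene(seed=7))


def random_mask(rng, shape=(32, 32), density=0.4) -> np.ndarray:
    return rng.random(shape) < density


def random_labels(rng, shape=(32, 32), n_blobs=4, radius=5) -> np.ndarray:
    """A few disjoint random discs, labelled 1..k in raster order."""
    from chipcyte.segment import label_components

    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for _ in range(n_blobs):
        cy, cx = rng.integers(0, shape[0]), rng.integers(0, shape[1])
        r = rng.integers(2, radius + 1)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return label_components(mask, 8)
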