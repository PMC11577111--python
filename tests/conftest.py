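import numpy as np
import pytest

from bodyatlas.containers import DisplacementField, Grid, Volume
from bodyatlas.phantom import PhantomSpec, make_template


@pytest.fixture(scope="session")
def small_grid():
    return Grid((16, 16, 16), (2.0, 2.0, 2.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def smooth_random_field(grid: Grid, amplitude_mm: float, seed: int) -> DisplacementField:
    """Smooth random displacement field for oracle tests (tapered at edges)."""
    from scipy import ndimage

    r = np.random.default_rng(seed)
    v = r.standard_normal(grid.shape + (3,))
    for d in range(3):
        v[..., d] = ndimage.gaussian_filter(v[..., d], 2.5, mode="constant")
    norm = np.sqrt((v**2).sum(axis=-1)).max()
    if norm > 0:
        v *= amplitude_mm / norm
    return DisplacementField(v, grid)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small phantom for fast end-to-end tests."""
    return PhantomSpec(
        shape=(32, 24, 48),
        spacing=(6.0, 6.0, 6.0),
        body_semi_axes=(80.0, 60.0, 135.0),
        shell_thickness=14.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_template(default_spec):
    return make_template(default_spec)


@pytest.fixture(scope="session")
def tiny_template(tiny_spec):
    return make_template(tiny_spec)
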