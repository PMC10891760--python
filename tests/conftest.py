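import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cine5d.data_model import CoilSet, ImageSeries5D, KSpace5D
from cine5d.synthetic import MaskSpec, PhantomSpec, generate_dataset

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def random_instance(rng, grid=(4, 4, 4), nr=2, nc=2, ncoils=2):
    """A random small multicoil problem with normalized coils and ~50% masks."""
    def cplx(shape):
        return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)

    maps = cplx((ncoils, *grid))
    maps /= np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    coils = CoilSet(maps=maps)
    masks = (rng.random((nr, nc, *grid)) < 0.5).astype(np.uint8)
    masks[..., 0, 0, 0] = 1  # never a fully empty frame
    m = ImageSeries5D(data=cplx((nr, nc, *grid)))
    ydata = cplx((nr, nc, ncoils, *grid)) * masks[:, :, None]
    y = KSpace5D(data=ydata, masks=masks)
    return m, y, coils, masks


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_problem():
    """8x8x4 grid, 6 cardiac x 2 respiratory phases, 2 coils, AF 2, noiseless."""
    spec = PhantomSpec(grid=(8, 8, 4), nc=6, nr=2, ncoils=2, seed=1)
    kspace, coils, truth = generate_dataset(spec, MaskSpec(af=2.0, seed=1))
    return kspace, coils, truth


@pytest.fixture(scope="session")
def full_mask_problem():
    """Single uniform coil, full sampling: E is a plain orthonormal DFT."""
    rng = np.random.default_rng(7)
    grid, nr, nc = (6, 6, 4), 1, 3
    truth = ImageSeries5D(
        data=rng.standard_normal((nr, nc, *grid))
        + 1j * rng.standard_normal((nr, nc, *grid))
    )
    coils = CoilSet(maps=np.ones((1, *grid), dtype=complex))
    masks = np.ones((nr, nc, *grid), dtype=np.uint8)
    return truth, coils, masks
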