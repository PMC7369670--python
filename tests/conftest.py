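import numpy as np
import pytest
from scipy import ndimage

from spinereg.transforms import AffineTransform, BSplineFFD
from spinereg.volumes import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(rng):
    return Volume(rng.uniform(0, 1, (10, 10, 10)))


@pytest.fixture
def smooth_pair():
    """Fixed/moving pair with a smooth non-monotone intensity relationship and
    densely occupied joint histogram (well-conditioned for gradient checks)."""
    rng = np.random.default_rng(3)
    nx = 8
    f = ndimage.gaussian_filter(rng.uniform(0, 1, (nx, nx, nx)), 1.0)
    m = np.sin(6 * f) + 0.3 * ndimage.gaussian_filter(
        rng.uniform(0, 1, (nx, nx, nx)), 1.0
    )
    fixed, moving = Volume(f), Volume(m)
    rf = (f.min() - 0.05 * np.ptp(f), f.max() + 0.05 * np.ptp(f))
    rm = (m.min() - 0.05 * np.ptp(m), m.max() + 0.05 * np.ptp(m))
    return fixed, moving, rf, rm


@pytest.fixture
def dense_grid_points():
    """Regular interior sample set with fractional offset 0.4 (off cell faces
    under the translations used in the gradient tests)."""
    nx = 8
    ii, jj, kk = np.meshgrid(*[np.arange(1, nx - 2)] * 3, indexing="ij")
    return np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1) + 0.4


@pytest.fixture
def small_ffd(rng):
    ffd = BSplineFFD(grid_origin=(-20, -20, -20), grid_spacing=(10, 10, 10),
                     grid_shape=(8, 8, 8))
    ffd.coefficients = rng.normal(0, 2, size=ffd.coefficients.shape)
    return ffd


@pytest.fixture
def identity_affine():
    return AffineTransform()
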