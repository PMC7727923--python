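import numpy as np
import pytest

from ctvent.grid import Grid, ImageVolume
from ctvent.phantom import PhantomSpec, generate_phantom
from ctvent.pipeline import (
    PHANTOM_KNOT_SPACING_MM,
    PHANTOM_SUBDOMAIN_SPACING_MM,
    PreparedCase,
)

# -- published per-case correlations used as worked-example inputs ----------
IJF_CORRELATIONS = [0.12, 0.86, 0.73, 0.90, 0.87, 0.64, 0.82, 0.79,
                    0.84, 0.44, 0.83, 0.90, 0.37, 0.25, 0.82]
MCVC_CORRELATIONS = [0.05, 0.48, 0.62, 0.10, 0.75, 0.50, 0.52, 0.08,
                     0.77, 0.84, -0.06, 0.33, 0.20, 0.06, 0.54]


def prepared_from_case(case, seed=5, displacement=None, **overrides):
    kw = dict(knot_spacing_mm=PHANTOM_KNOT_SPACING_MM,
              subdomain_spacing_mm=PHANTOM_SUBDOMAIN_SPACING_MM, seed=seed)
    kw.update(overrides)
    return PreparedCase(case.reference_image, case.target_image, case.mask_R,
                        case.mask_T,
                        displacement if displacement is not None
                        else case.inverse_displacement, **kw)


@pytest.fixture(scope="session")
def scale_phantom():
    """Noise-free uniform 1.331-fold expansion on the default grid."""
    spec = PhantomSpec(deformation="uniform_scale", scale=(1.1, 1.1, 1.1),
                       hu_noise_sd=0.0, seed=1)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def scale_prepared(scale_phantom):
    return prepared_from_case(scale_phantom)


@pytest.fixture(scope="session")
def sinusoid_phantom():
    """Noise-free separable sinusoid warp, clinical-scale voxel volume."""
    spec = PhantomSpec(grid_dims=(96, 96, 72), spacing_mm=(2.0, 2.0, 2.0),
                       deformation="sinusoid", amplitude_mm=(2.0, 2.0, 2.0),
                       wavelength_mm=(40.0, 40.0, 40.0), hu_noise_sd=0.0,
                       seed=11)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def sinusoid_prepared(sinusoid_phantom):
    return prepared_from_case(sinusoid_phantom)


@pytest.fixture(scope="session")
def tiny_phantom():
    """Small, fast case for pipeline and I/O tests."""
    spec = PhantomSpec(grid_dims=(32, 32, 24), spacing_mm=(3.0, 3.0, 3.0),
                       deformation="sinusoid", amplitude_mm=(1.5, 1.5, 1.5),
                       wavelength_mm=(36.0, 36.0, 36.0), seed=7)
    return generate_phantom(spec)


@pytest.fixture
def random_mask():
    """A small connected blob mask for sampling/MLS unit tests."""
    grid = Grid((12, 12, 10), (2.0, 2.0, 2.0))
    ii, jj, kk = np.indices(grid.shape)
    blob = ((ii - 5.5) ** 2 / 25 + (jj - 5.5) ** 2 / 25 + (kk - 4.5) ** 2 / 16) <= 1.0
    return ImageVolume(blob, grid)
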