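import numpy as np
import pytest

import petresponse as pr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sphere_pair(
    suv_t1=10.0,
    suv_t2=3.0,
    radius=10.0,
    background=2.0,
    psf_fwhm=0.0,
    noise_sigma=0.0,
    grid=48,
    spacing=2.0,
    misalignment=None,
    seed=1,
):
    """Single centered spherical lesion on a cubic grid."""
    center = ((grid - 1) * spacing / 2.0,) * 3
    spec = pr.PhantomSpec(
        grid_shape=(grid,) * 3,
        spacing=(spacing,) * 3,
        background_suv=background,
        lesions=[
            pr.LesionSpec(
                center=center, radius=radius, suv_t1=suv_t1, suv_t2=suv_t2,
                lesion_id="L1",
            )
        ],
        psf_fwhm=psf_fwhm,
        noise_sigma=noise_sigma,
        misalignment=misalignment,
        seed=seed,
    )
    return pr.generate_pair(spec)


@pytest.fixture
def sphere_pair():
    """Noiseless, unblurred 10 mm sphere, SUV 10 -> 3 on background 2."""
    return make_sphere_pair()


@pytest.fixture
def center_seed():
    return (23, 23, 23)


def true_sphere_mask(volume, center, radius):
    grid = volume.coordinate_grid()
    d2 = ((grid - np.asarray(center)) ** 2).sum(axis=-1)
    return d2 <= radius**2
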