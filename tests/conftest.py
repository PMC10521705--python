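"""Shared fixtures: small deterministic phantoms reused across test modules."""

import numpy as np
import pytest

from stresskit import PhantomParams, generate_phantom, make_fake_skull

#: Compact phantom geometry used throughout the unit tests (fast, leaves a
#: full 10-voxel exterior band for the fake skull).
SMALL_KW = dict(
    grid_shape=(64, 64, 64),
    brain_semiaxes=(22.0, 26.0, 20.0),
    tumor_center=(6.0, 3.0, 2.0),
    tumor_radius=8.0,
)


@pytest.fixture(scope="session")
def gbm_study():
    return generate_phantom(PhantomParams(grade_label="GBM-like", rng_seed=7, **SMALL_KW))


@pytest.fixture(scope="session")
def lgg_study():
    return generate_phantom(PhantomParams(grade_label="LGG-like", rng_seed=7, **SMALL_KW))


@pytest.fixture(scope="session")
def skulled_study(gbm_study):
    """GBM phantom with the fake skull added, plus the candidate shell mask."""
    return make_fake_skull(gbm_study)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def smooth_blob(shape=(32, 32, 32), seed=0):
    """A smooth positive test volume (Gaussian bump + low-frequency texture)."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    c = [(s - 1) / 2 for s in shape]
    d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
    base = 100.0 * np.exp(-d2 / (2.0 * (min(shape) / 6.0) ** 2))
    texture = 1.0 + 0.05 * ndimage.gaussian_filter(rng.standard_normal(shape), 4.0)
    # compact support: the envelope tapers to ~0 well inside the field of view
    return np.clip(base * texture, 0, None)
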