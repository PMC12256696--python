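import numpy as np
import pytest

from latticeplan.grids import BinaryMask, DoseGrid, ImageVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    """Random 8^3 HU volume on a 2 mm grid."""
    return ImageVolume(rng.normal(40.0, 200.0, (8, 8, 8)), (2, 2, 2), (0, 0, 0))


@pytest.fixture
def small_pair(rng):
    x = ImageVolume(rng.normal(40.0, 200.0, (8, 8, 8)), (2, 2, 2), (0, 0, 0))
    y = ImageVolume(rng.normal(40.0, 200.0, (8, 8, 8)), (2, 2, 2), (0, 0, 0))
    return x, y


def make_registration_pairs(base_seed, n, noise_sd=2.0, grid_shape=(64, 64, 32)):
    """Couch-removed dCT/pCT phantom pairs for DVF-model experiments.

    Fine 3x3x4 mm spacing (so the <= 5 mm deformations exceed the trilinear
    interpolation floor), torso capped inside the grid in z, deformation =
    4 mm systematic sag + 1 mm random residual.
    """
    from latticeplan.phantom import PhantomSpec, make_phantom
    from latticeplan.preprocess import remove_couch

    pairs, bundles = [], []
    for i in range(n):
        spec = PhantomSpec(
            grid_shape=grid_shape, spacing=(3.0, 3.0, 4.0),
            body_semiaxes_mm=(80.0, 55.0), lung_semiaxes_mm=(30.0, 35.0, 50.0),
            body_z_halfextent_mm=56.0,
            gtv_center_mm=(30.0, 5.0, 0.0), gtv_semiaxes_mm=(22.0, 20.0, 20.0),
            sag_amplitude_mm=4.0, deform_amplitude_mm=1.0, noise_sd=noise_sd,
            seed=(base_seed * 1000 + i) % (2 ** 31),
        )
        b = make_phantom(spec)
        d, _ = remove_couch(b.dct)
        p, _ = remove_couch(b.pct)
        pairs.append((d, p))
        bundles.append(b)
    return pairs, bundles


def make_dose(arr, spacing=(1, 1, 1), origin=(0, 0, 0)):
    return DoseGrid(np.asarray(arr, dtype=float), spacing, origin)


def make_mask(arr, spacing=(1, 1, 1), origin=(0, 0, 0)):
    return BinaryMask(np.asarray(arr, dtype=np.uint8), spacing, origin)
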