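"""Digital phantom generator: determinism, geometry, deformation, dose painting."""

import numpy as np
import pytest

from latticeplan.grids import BinaryMask, ImageVolume
from latticeplan.metrics import mae
from latticeplan.phantom import (
    OarSpec,
    PhantomSpec,
    augment,
    ellipsoid_mask,
    make_known_dvf,
    make_phantom,
    synth_lattice_dose,
)
from latticeplan.lattice import SphereSet

SMALL = dict(grid_shape=(48, 48, 24), spacing=(8.0, 8.0, 10.0))


class TestMakePhantom:
    def test_same_seed_bit_identical(self):
        a = make_phantom(PhantomSpec(seed=5, **SMALL))
        b = make_phantom(PhantomSpec(seed=5, **SMALL))
        assert np.array_equal(a.dct.voxels, b.dct.voxels)
        assert np.array_equal(a.pct.voxels, b.pct.voxels)
        assert np.array_equal(a.true_dvf.voxels, b.true_dvf.voxels)
        assert np.array_equal(a.gtv.voxels, b.gtv.voxels)

    def test_null_deformation_identical_couch(self):
        spec = PhantomSpec(seed=1, deform_amplitude_mm=0, sag_amplitude_mm=0,
                           couch_dct="flat", couch_pct="flat", noise_sd=10.0, **SMALL)
        b = make_phantom(spec)
        assert mae(b.dct, b.pct) <= 3 * spec.noise_sd

    def test_gas_pocket_localized_hu_change(self):
        base = dict(region="abdomen", seed=2, deform_amplitude_mm=0, sag_amplitude_mm=0,
                    couch_dct="flat", couch_pct="flat", noise_sd=2.0,
                    gas_center_mm=(60.0, -20.0, 0.0), gas_radius_mm=30.0,
                    grid_shape=(64, 64, 32), spacing=(6.0, 6.0, 8.0))
        b = make_phantom(PhantomSpec(gas_pocket=True, **base))
        pocket = ellipsoid_mask(b.dct, base["gas_center_mm"], (20.0,) * 3)  # core of pocket
        outside = BinaryMask(b.body.voxels & ~pocket.voxels
                             & ~ellipsoid_mask(b.dct, base["gas_center_mm"], (40.0,) * 3).voxels,
                             b.body.spacing, b.body.origin)
        assert mae(b.dct, b.pct, pocket) >= 200.0  # air vs soft tissue in the pocket
        assert mae(b.dct, b.pct, outside) < 50.0

    def test_gtv_outside_body_rejected(self):
        with pytest.raises(ValueError):
            make_phantom(PhantomSpec(gtv_center_mm=(140, 80, 0), **SMALL))

    def test_true_dvf_maps_dct_onto_pct_anatomy(self):
        from latticeplan.grids import warp

        spec = PhantomSpec(seed=3, noise_sd=0.0, couch_dct="none", couch_pct="none",
                           grid_shape=(64, 64, 32), spacing=(3.0, 3.0, 4.0),
                           body_semiaxes_mm=(80.0, 55.0), lung_semiaxes_mm=(30.0, 35.0, 50.0),
                           body_z_halfextent_mm=56.0,
                           gtv_center_mm=(30.0, 5.0, 0.0), gtv_semiaxes_mm=(22.0, 20.0, 20.0),
                           sag_amplitude_mm=4.0, deform_amplitude_mm=1.0)
        b = make_phantom(spec)
        warped = warp(b.dct, b.true_dvf)
        # warping the dCT by the ground-truth field must beat no warp; the
        # residual is trilinear interpolation error at tissue boundaries
        assert mae(warped, b.pct) < mae(b.dct, b.pct)
        assert mae(warped, b.pct) < 15.0

    def test_oar_masks_generated(self):
        spec = PhantomSpec(seed=4, oars=(OarSpec("cord", "cylinder", (0, 59, 0), 8.0),),
                           **SMALL)
        b = make_phantom(spec)
        assert "cord" in b.oars and b.oars["cord"].voxels.sum() > 0


class TestKnownDvf:
    def test_zero_amplitude_zero_field(self, small_volume):
        f = make_known_dvf(small_volume, 0.0, 20.0, seed=1)
        assert not f.voxels.any()

    def test_amplitude_bound(self, small_volume):
        f = make_known_dvf(small_volume, 5.0, 20.0, seed=1)
        assert f.magnitude.max() <= 5.0 + 1e-9

    def test_seed_determinism_and_variation(self, small_volume):
        a = make_known_dvf(small_volume, 5.0, 20.0, seed=1)
        b = make_known_dvf(small_volume, 5.0, 20.0, seed=1)
        c = make_known_dvf(small_volume, 5.0, 20.0, seed=2)
        assert np.array_equal(a.voxels, b.voxels)
        assert not np.array_equal(a.voxels, c.voxels)

    def test_negative_amplitude_rejected(self, small_volume):
        with pytest.raises(ValueError):
            make_known_dvf(small_volume, -1.0, 20.0, seed=0)


class TestAugment:
    def test_rotate90_four_times_is_identity(self, rng):
        v = ImageVolume(rng.normal(0, 100, (12, 12, 4)), (1, 1, 1), (0, 0, 0))
        out = v
        for _ in range(4):
            out = augment(out, "rotate90")
        assert np.array_equal(out.voxels, v.voxels)

    def test_crop128_centered(self, rng):
        v = ImageVolume(rng.normal(0, 100, (256, 256, 4)), (1, 1, 1), (0, 0, 0))
        out = augment(v, "crop128")
        assert out.shape == (128, 128, 4)
        assert np.array_equal(out.voxels, v.voxels[64:192, 64:192, :])

    def test_crop128_window_must_fit(self, rng):
        v = ImageVolume(rng.normal(0, 100, (100, 100, 4)), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValueError):
            augment(v, "crop128")

    def test_translate_roundtrip_identity_on_interior(self, rng):
        v = ImageVolume(rng.normal(0, 100, (10, 10, 6)), (1, 1, 1), (0, 0, 0))
        out = augment(augment(v, "translate", (2, 0, 0)), "translate", (-2, 0, 0))
        assert np.array_equal(out.voxels[:-2], v.voxels[:-2])


class TestSynthLatticeDose:
    def _gtv(self):
        ref = ImageVolume(np.zeros((80, 80, 60)), (2, 2, 2), (-79, -79, -59))
        return ellipsoid_mask(ref, (0, 0, 0), (60, 55, 50))

    def test_single_sphere_valley_ratio(self):
        gtv = self._gtv()
        s = SphereSet(np.array([[0.0, 0.0, 0.0]]), 15.0)
        d = synth_lattice_dose(s, gtv, 2000.0, valley_ratio=0.3)
        pts = gtv.voxel_centers_mm()
        r = np.linalg.norm(pts, axis=-1)
        inter = gtv.astype_bool() & (r > 30.0)  # inside GTV, away from the sphere
        ratio = d.voxels[inter].min() / 2000.0
        assert 0.28 <= ratio <= 0.32

    def test_center_dose_at_least_prescription(self):
        gtv = self._gtv()
        s = SphereSet(np.array([[0.0, 0.0, 0.0]]), 15.0)
        d = synth_lattice_dose(s, gtv, 2000.0, valley_ratio=0.3)
        idx = tuple(np.rint(gtv.world_to_index([0, 0, 0])).astype(int))
        assert d.voxels[idx] >= 2000.0

    def test_sphere_median_equals_prescription(self):
        gtv = self._gtv()
        s = SphereSet(np.array([[0.0, 0.0, 0.0]]), 15.0)
        d = synth_lattice_dose(s, gtv, 2000.0, valley_ratio=0.35)
        pts = gtv.voxel_centers_mm()
        inside = np.linalg.norm(pts, axis=-1) <= 7.5
        med = np.median(d.voxels[inside])
        assert abs(med - 2000.0) / 2000.0 < 0.01

    def test_linearity_in_prescription(self):
        gtv = self._gtv()
        s = SphereSet(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, -30.0]]), 15.0)
        d1 = synth_lattice_dose(s, gtv, 1000.0, valley_ratio=0.3)
        d2 = synth_lattice_dose(s, gtv, 2000.0, valley_ratio=0.3)
        assert np.allclose(d2.voxels, 2 * d1.voxels, rtol=1e-5, atol=1e-3)

    def test_empty_sphere_set_warns_all_valley(self):
        gtv = self._gtv()
        with pytest.warns(UserWarning):
            d = synth_lattice_dose(SphereSet(np.empty((0, 3))), gtv, 2000.0, 0.3)
        inside = gtv.astype_bool()
        assert np.allclose(d.voxels[inside], 600.0, rtol=1e-6)

    def test_dose_decays_outside_gtv(self):
        gtv = self._gtv()
        s = SphereSet(np.array([[0.0, 0.0, 0.0]]), 15.0)
        d = synth_lattice_dose(s, gtv, 2000.0, 0.3)
        corner = d.voxels[0, 0, 0]
        assert corner < 0.1 * 2000.0

    def test_invalid_params_rejected(self):
        gtv = self._gtv()
        s = SphereSet(np.array([[0.0, 0.0, 0.0]]), 15.0)
        with pytest.raises(ValueError):
            synth_lattice_dose(s, gtv, 2000.0, valley_ratio=1.5)
        with pytest.raises(ValueError):
            synth_lattice_dose(s, gtv, 2000.0, valley_ratio=0.3, peak_factor=0.5)
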