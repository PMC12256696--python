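"""Raster types, resampling, warping, rigid maps and NIfTI round-trips."""

import numpy as np
import pytest

from latticeplan.grids import (
    AIR_HU,
    BinaryMask,
    DeformationField,
    DoseGrid,
    ImageVolume,
    RigidTransform,
    apply_rigid,
    read_dose,
    read_mask,
    read_volume,
    resample_to_shape,
    warp,
    write_dose,
    write_mask,
    write_volume,
)


class TestTypes:
    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            ImageVolume(np.zeros((4, 4, 4)), (1, 0, 1), (0, 0, 0))

    def test_mask_values_restricted(self):
        with pytest.raises(ValueError):
            BinaryMask(np.full((3, 3, 3), 2), (1, 1, 1), (0, 0, 0))

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            DoseGrid(np.full((3, 3, 3), -1.0), (1, 1, 1), (0, 0, 0))

    def test_voxel_center_convention(self):
        v = ImageVolume(np.zeros((4, 4, 4)), (2, 3, 4), (10, 20, 30))
        assert np.allclose(v.index_to_world([1, 1, 1]), [12, 23, 34])
        assert np.allclose(v.world_to_index([12, 23, 34]), [1, 1, 1])


class TestResample:
    def test_constant_volume_stays_constant(self):
        v = ImageVolume(np.full((32, 32, 16), 40.0), (2, 2, 4), (0, 0, 0))
        out = resample_to_shape(v, (128, 128, 64))
        assert out.shape == (128, 128, 64)
        assert np.allclose(out.voxels, 40.0, atol=1e-9)

    def test_training_resolution_and_fov_preserved(self):
        v = ImageVolume(np.zeros((192, 192, 96)), (2, 2, 3), (0, 0, 0))
        out = resample_to_shape(v, (128, 128, 64))
        assert out.shape == (128, 128, 64)
        # physical extent (shape * spacing) unchanged
        assert np.allclose(np.array(out.shape) * out.spacing,
                           np.array(v.shape) * v.spacing)

    def test_linear_ramp_interpolates_exactly(self):
        # HU = 3*z_mm: trilinear resampling reproduces the ramp at new centers
        v = ImageVolume(np.zeros((16, 16, 32)), (2, 2, 2), (0, 0, 5))
        z = v.voxel_centers_mm()[..., 2]
        v = ImageVolume(3.0 * z, (2, 2, 2), (0, 0, 5))
        out = resample_to_shape(v, (8, 8, 16))
        expect = 3.0 * out.voxel_centers_mm()[..., 2]
        interior = (slice(1, -1),) * 3
        assert np.abs(out.voxels[interior] - expect[interior]).max() < 1e-4

    def test_mask_stays_binary(self, rng):
        m = BinaryMask((rng.random((16, 16, 8)) > 0.5).astype(np.uint8), (2, 2, 2), (0, 0, 0))
        out = resample_to_shape(m, (11, 9, 5))
        assert set(np.unique(out.voxels)) <= {0, 1}

    def test_invalid_shape_rejected(self, small_volume):
        with pytest.raises(ValueError):
            resample_to_shape(small_volume, (0, 8, 8))


class TestWarp:
    def test_zero_dvf_is_identity(self, small_volume):
        dvf = DeformationField(np.zeros(small_volume.shape + (3,)),
                               small_volume.spacing, small_volume.origin)
        out = warp(small_volume, dvf)
        assert np.array_equal(out.voxels, small_volume.voxels)

    def test_integer_voxel_shift(self, small_volume):
        u = np.zeros(small_volume.shape + (3,))
        u[..., 0] = small_volume.spacing[0]  # +1 voxel along x
        out = warp(small_volume, DeformationField(u, small_volume.spacing, small_volume.origin))
        assert np.allclose(out.voxels[:-1], small_volume.voxels[1:])
        assert np.all(out.voxels[-1] == AIR_HU)

    def test_matches_bruteforce_trilinear_oracle(self, rng):
        from scipy import ndimage as ndi

        n = 16
        vox = rng.normal(0, 100, (n, n, n))
        v = ImageVolume(vox, (2, 2, 2), (0, 0, 0))
        u = np.stack([ndi.gaussian_filter(rng.normal(0, 1, (n, n, n)), 2) for _ in range(3)],
                     axis=-1) * 3.0
        dvf = DeformationField(u, v.spacing, v.origin)
        out = warp(v, dvf)

        def trilinear(vol, x, y, z):
            if not (0 <= x <= n - 1 and 0 <= y <= n - 1 and 0 <= z <= n - 1):
                # partial oracle: skip boundary-crossing samples
                return None
            i, j, k = int(np.floor(min(x, n - 2))), int(np.floor(min(y, n - 2))), int(np.floor(min(z, n - 2)))
            fx, fy, fz = x - i, y - j, z - k
            acc = 0.0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        w = ((fx if dx else 1 - fx) * (fy if dy else 1 - fy)
                             * (fz if dz else 1 - fz))
                        acc += w * vol[i + dx, j + dy, k + dz]
            return acc

        checked = 0
        vfl = np.asarray(v.voxels, dtype=float)
        for i in range(0, n, 3):
            for j in range(0, n, 3):
                for k in range(0, n, 3):
                    x = i + u[i, j, k, 0] / 2.0
                    y = j + u[i, j, k, 1] / 2.0
                    z = k + u[i, j, k, 2] / 2.0
                    ref = trilinear(vfl, x, y, z)
                    if ref is None:
                        continue
                    assert abs(out.voxels[i, j, k] - ref) < 1e-4
                    checked += 1
        assert checked > 50


class TestRigid:
    def test_identity_returns_input(self, small_volume):
        out = apply_rigid(small_volume, RigidTransform.identity())
        assert np.allclose(out.voxels, small_volume.voxels, atol=1e-6)

    def test_translation_roundtrip(self, rng):
        from scipy import ndimage as ndi

        vox = ndi.gaussian_filter(rng.normal(0, 200, (24, 24, 24)), 3.5)
        v = ImageVolume(vox, (2, 2, 2), (0, 0, 0))
        t = RigidTransform((0, 0, 0), (5, -3, 2))
        back = apply_rigid(apply_rigid(v, t), t.inverse())
        interior = (slice(4, -4),) * 3
        assert np.abs(back.voxels[interior] - v.voxels[interior]).max() < 1.0

    def test_inverse_composes_to_identity(self):
        t = RigidTransform((10, -5, 30), (4, 2, -7))
        pts = np.random.default_rng(0).normal(0, 50, (20, 3))
        c = np.array([1.0, 2.0, 3.0])
        round_trip = t.inverse().map_points(t.map_points(pts, c), c)
        assert np.abs(round_trip - pts).max() < 1e-9

    def test_rot90_permutes_box_axes(self):
        # axis-aligned box, 90 deg about z: x/y axes swap as an index permutation
        vox = np.zeros((21, 21, 5))
        vox[7:14, 3:18, :] = 500.0  # extent 7 in x, 15 in y
        v = ImageVolume(vox, (1, 1, 1), (-10, -10, -2))
        out = apply_rigid(v, RigidTransform((0, 0, 90), (0, 0, 0)))
        # oracle: rotating the sampling grid by 90 deg about the center maps
        # the box onto its transpose (up to index flip)
        got = out.voxels > 250
        ref = np.zeros_like(got)
        ref[3:18, 7:14, :] = True
        # allow a 1-voxel boundary band from interpolation
        assert (got ^ ref).sum() <= 2 * (2 * (7 + 15)) * 5


class TestIO:
    def test_volume_roundtrip_bitexact(self, tmp_path, rng):
        v = ImageVolume(rng.normal(0, 500, (16, 16, 16)), (1.5, 2.0, 2.5), (5, -7, 3))
        path = tmp_path / "v.nii.gz"
        write_volume(v, path)
        r = read_volume(path)
        assert np.array_equal(r.voxels, v.voxels)
        assert np.allclose(r.spacing, v.spacing, atol=1e-6)
        assert np.allclose(r.origin, v.origin, atol=1e-6)

    def test_mask_and_dose_roundtrip(self, tmp_path, rng):
        m = BinaryMask((rng.random((8, 8, 8)) > 0.5).astype(np.uint8), (1, 1, 1), (0, 0, 0))
        d = DoseGrid(rng.random((8, 8, 8)) * 2000, (2, 2, 2), (-4, 0, 4))
        write_mask(m, tmp_path / "m.nii.gz")
        write_dose(d, tmp_path / "d.nii.gz")
        assert np.array_equal(read_mask(tmp_path / "m.nii.gz").voxels, m.voxels)
        # dose in cGy round-trips with no unit rescaling
        assert np.array_equal(read_dose(tmp_path / "d.nii.gz").voxels, d.voxels)

    def test_missing_file_errors_with_path(self, tmp_path):
        with pytest.raises(IOError, match="nothere"):
            read_volume(tmp_path / "nothere.nii.gz")

    def test_nonpositive_spacing_rejected_on_read(self, tmp_path):
        import json

        (tmp_path / "bad.json").write_text(json.dumps(
            {"spacing": [1, 0, 1], "data": [[[0.0]]]}))
        with pytest.raises(IOError):
            read_volume(tmp_path / "bad.json")

    def test_json_sidecar_fixture(self, tmp_path):
        import json

        data = [[[0.0, 1.0], [2.0, 3.0]], [[4.0, 5.0], [6.0, 7.0]]]
        (tmp_path / "a.json").write_text(json.dumps(
            {"spacing": [1, 2, 3], "origin": [0, 0, 0], "data": data}))
        v = read_volume(tmp_path / "a.json")
        assert v.shape == (2, 2, 2)
        assert v.voxels[1, 0, 1] == 5.0
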