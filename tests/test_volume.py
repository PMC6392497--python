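"""Volume I/O, averaging, normalization, masking and montage export."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import voxatlas as va
from voxatlas.volume import export_texture_atlas

GRID = va.VoxelGrid((10, 10, 10), (1.0, 1.0, 2.0))


class TestIO:
    def test_round_trip_is_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        data = rng.integers(0, 2**16, size=GRID.dims).astype(np.uint16)
        vol = va.Volume(GRID, data, value_kind="raw")
        path = va.write_volume(vol, tmp_path / "v.nii.gz")
        back = va.read_volume(path)
        assert back.data.dtype == np.uint16
        np.testing.assert_array_equal(back.data, data)
        assert back.grid.compatible(GRID)

    def test_normalized8_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        data = rng.integers(0, 256, size=GRID.dims).astype(np.uint8)
        vol = va.Volume(GRID, data, value_kind="normalized8")
        back = va.read_volume(va.write_volume(vol, tmp_path / "v.nii.gz"),
                              value_kind="normalized8")
        np.testing.assert_array_equal(back.data, data)

    def test_expect_grid_mismatch_raises(self, tmp_path):
        vol = va.Volume(GRID, np.zeros(GRID.dims))
        path = va.write_volume(vol, tmp_path / "v.nii.gz")
        wrong = va.VoxelGrid((5, 10, 10), GRID.spacing_um)
        with pytest.raises(va.GridMismatchError, match="dims"):
            va.read_volume(path, expect_grid=wrong)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(va.DataError, match="not found"):
            va.read_volume(tmp_path / "nope.nii.gz")

    def test_non_3d_rejected(self, tmp_path):
        import nibabel as nib

        img = nib.Nifti1Image(np.zeros((4, 4)), np.eye(4))
        nib.save(img, str(tmp_path / "flat.nii.gz"))
        with pytest.raises(va.DataError, match="3D"):
            va.read_volume(tmp_path / "flat.nii.gz")


class TestAverage:
    def test_identical_volumes_are_fixed_point(self):
        v = va.Volume(GRID, np.full(GRID.dims, 7.0))
        out = va.average_scans([v, v, v])
        np.testing.assert_allclose(out.data, 7.0)

    def test_arithmetic_mean_of_constants(self):
        a = va.Volume(GRID, np.full(GRID.dims, 100.0))
        b = va.Volume(GRID, np.full(GRID.dims, 200.0))
        with pytest.warns(UserWarning, match="at least 3"):
            out = va.average_scans([a, b])
        np.testing.assert_allclose(out.data, 150.0)

    def test_matches_per_voxel_loop_oracle(self):
        rng = np.random.default_rng(2)
        vols = [va.Volume(GRID, rng.integers(0, 1000, GRID.dims).astype(float))
                for _ in range(3)]
        out = va.average_scans(vols)
        expected = np.zeros(GRID.dims)
        for x in range(10):
            for y in range(10):
                for z in range(10):
                    expected[x, y, z] = sum(v.data[x, y, z] for v in vols) / 3
        np.testing.assert_allclose(out.data, expected, rtol=1e-9)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(3)
        vols = [va.Volume(GRID, rng.random(GRID.dims)) for _ in range(4)]
        a = va.average_scans(vols)
        b = va.average_scans(vols[::-1])
        np.testing.assert_allclose(a.data, b.data)

    def test_empty_list_rejected(self):
        with pytest.raises(va.DataError):
            va.average_scans([])

    def test_incompatible_grids_rejected(self):
        other = va.VoxelGrid((10, 10, 10), (2.0, 2.0, 2.0))
        with pytest.raises(va.GridMismatchError):
            va.average_scans([va.Volume(GRID, np.zeros(GRID.dims)),
                              va.Volume(other, np.zeros(other.dims))])


class TestNormalize:
    def test_all_zero_stays_zero(self):
        out = va.normalize_to_8bit(va.Volume(GRID, np.zeros(GRID.dims)))
        assert out.value_kind == "normalized8"
        assert not out.data.any()

    def test_constant_positive_maps_to_255(self):
        out = va.normalize_to_8bit(va.Volume(GRID, np.full(GRID.dims, 3.0)))
        assert (out.data == 255).all()

    def test_ramp_matches_quantile_clip_oracle(self):
        grid = va.VoxelGrid((100, 100, 1), (1, 1, 1))
        ramp = np.arange(10_000, dtype=np.float64).reshape(grid.dims)
        out = va.normalize_to_8bit(va.Volume(grid, ramp), saturation_fraction=1e-4)
        # independent oracle: explicit quantile + clip + rescale
        q = np.quantile(ramp.ravel(), 1 - 1e-4)
        oracle = np.clip(np.rint(255 * np.minimum(ramp, q) / q), 0, 255)
        np.testing.assert_array_equal(out.data, oracle.astype(np.uint8))
        assert (out.data[ramp >= q] == 255).all()

    def test_mask_domain_uses_masked_quantile(self):
        data = np.zeros(GRID.dims)
        data[:5] = 100.0
        data[5:] = 1000.0  # bright voxels outside the mask
        mask = va.Volume(GRID, (np.arange(10) < 5)[:, None, None]
                         * np.ones((1, 10, 10), dtype=int), value_kind="binary")
        out = va.normalize_to_8bit(va.Volume(GRID, data), domain="mask", mask=mask)
        assert (out.data[:5] == 255).all()

    def test_empty_mask_rejected(self):
        mask = va.Volume(GRID, np.zeros(GRID.dims, dtype=int), value_kind="binary")
        with pytest.raises(va.DataError, match="empty"):
            va.normalize_to_8bit(va.Volume(GRID, np.ones(GRID.dims)),
                                 domain="mask", mask=mask)

    def test_negative_values_rejected(self):
        with pytest.raises(va.DataError):
            va.normalize_to_8bit(va.Volume(GRID, np.full(GRID.dims, -1.0)))

    @given(st.integers(0, 2**31 - 1))
    def test_monotone_and_saturating(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.integers(0, 5000, size=(6, 6, 6)).astype(float)
        grid = va.VoxelGrid((6, 6, 6), (1, 1, 1))
        out = va.normalize_to_8bit(va.Volume(grid, data)).data
        order = np.argsort(data.ravel())
        assert (np.diff(out.ravel()[order].astype(int)) >= 0).all()
        if data.max() > 0:
            assert out.max() == 255


class TestApplyMask:
    def test_full_mask_is_identity(self):
        v = va.Volume(GRID, np.arange(1000).reshape(GRID.dims))
        full = va.Volume(GRID, np.ones(GRID.dims, dtype=int), value_kind="binary")
        np.testing.assert_array_equal(va.apply_mask(v, full).data, v.data)

    def test_empty_mask_zeroes_everything(self):
        v = va.Volume(GRID, np.arange(1000).reshape(GRID.dims))
        empty = va.Volume(GRID, np.zeros(GRID.dims, dtype=int), value_kind="binary")
        assert not va.apply_mask(v, empty).data.any()

    def test_matches_elementwise_multiply_oracle_and_idempotent(self):
        rng = np.random.default_rng(4)
        v = va.Volume(GRID, rng.integers(0, 255, GRID.dims))
        m = va.Volume(GRID, rng.integers(0, 2, GRID.dims), value_kind="binary")
        out = va.apply_mask(v, m)
        np.testing.assert_array_equal(out.data, v.data * m.data)
        np.testing.assert_array_equal(va.apply_mask(out, m).data, out.data)
        # output supported on the mask
        assert not out.data[m.data == 0].any()

    def test_non_binary_mask_rejected(self):
        v = va.Volume(GRID, np.zeros(GRID.dims))
        bad = va.Volume(GRID, np.full(GRID.dims, 2))
        with pytest.raises(va.DataError, match="binary"):
            va.apply_mask(v, bad)


class TestTextureAtlas:
    def test_400_plane_volume_gives_100_slices(self):
        grid = va.VoxelGrid((8, 8, 400), (1, 1, 1))
        vol = va.Volume(grid, np.zeros(grid.dims, dtype=np.uint8),
                        value_kind="normalized8")
        montage, n_slices = export_texture_atlas(vol, z_step=4, grid_cols=10,
                                                 grid_rows=10)
        assert n_slices == 100
        assert montage.shape == (80, 80)

    def test_single_plane_montage_equals_plane(self):
        grid = va.VoxelGrid((5, 7, 1), (1, 1, 1))
        rng = np.random.default_rng(5)
        vol = va.Volume(grid, rng.integers(0, 255, grid.dims).astype(np.uint8),
                        value_kind="normalized8")
        montage, n = export_texture_atlas(vol, z_step=1, grid_cols=1, grid_rows=1,
                                          scale=1.0)
        assert n == 1
        np.testing.assert_array_equal(montage, vol.data[:, :, 0].T)

    def test_tiles_match_every_4th_plane(self):
        grid = va.VoxelGrid((6, 4, 32), (1, 1, 1))
        rng = np.random.default_rng(6)
        vol = va.Volume(grid, rng.integers(0, 255, grid.dims).astype(np.uint8),
                        value_kind="normalized8")
        montage, n = export_texture_atlas(vol, z_step=4, grid_cols=3, grid_rows=3,
                                          scale=1.0)
        assert n == 8
        for k in range(9):
            r, c = divmod(k, 3)
            tile = montage[r * 4:(r + 1) * 4, c * 6:(c + 1) * 6]
            if k < 8:
                np.testing.assert_array_equal(tile, vol.data[:, :, 4 * k].T)
            else:
                assert not tile.any()  # unused tile zero-filled

    def test_too_many_slices_rejected(self):
        grid = va.VoxelGrid((4, 4, 100), (1, 1, 1))
        vol = va.Volume(grid, np.zeros(grid.dims))
        with pytest.raises(va.DataError, match="fit"):
            export_texture_atlas(vol, z_step=1, grid_cols=3, grid_rows=3)

    def test_bad_scale_rejected(self):
        grid = va.VoxelGrid((4, 4, 4), (1, 1, 1))
        vol = va.Volume(grid, np.zeros(grid.dims))
        with pytest.raises(va.DataError, match="scale"):
            export_texture_atlas(vol, scale=0.0)
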