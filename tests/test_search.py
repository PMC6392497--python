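"""Bit packing, fragment building and spatial search vs the brute oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import voxatlas as va
from voxatlas.search import BLOCK_BYTES, pack_block, unpack_block


def naive_pack(bits):
    """Independent bit packer: enumerate cells x-fastest, LSB-first."""
    out = bytearray(64)
    k = 0
    for z in range(8):
        for y in range(8):
            for x in range(8):
                if bits[x, y, z]:
                    out[k // 8] |= 1 << (k % 8)
                k += 1
    return bytes(out)


class TestPackBlock:
    def test_all_zeros(self):
        assert pack_block(np.zeros((8, 8, 8), dtype=int)) == b"\x00" * 64

    def test_all_ones(self):
        assert pack_block(np.ones((8, 8, 8), dtype=int)) == b"\xff" * 64

    def test_origin_voxel_sets_lsb_of_byte_zero(self):
        bits = np.zeros((8, 8, 8), dtype=int)
        bits[0, 0, 0] = 1
        payload = pack_block(bits)
        assert payload == b"\x01" + b"\x00" * 63
        np.testing.assert_array_equal(unpack_block(payload), bits)

    def test_matches_independent_naive_packer(self):
        rng = np.random.default_rng(7)
        for _ in range(32):
            bits = rng.integers(0, 2, size=(8, 8, 8))
            assert pack_block(bits) == naive_pack(bits)

    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_identity(self, seed):
        bits = np.random.default_rng(seed).integers(0, 2, size=(8, 8, 8))
        np.testing.assert_array_equal(unpack_block(pack_block(bits)), bits)

    def test_wrong_shape_rejected(self):
        with pytest.raises(va.DataError, match="8, 8, 8"):
            pack_block(np.zeros((4, 8, 8)))


class TestBinarize:
    GRID = va.VoxelGrid((9, 7, 5), (1, 1, 1))

    def _vol(self, seed=8):
        rng = np.random.default_rng(seed)
        return va.Volume(self.GRID, rng.integers(0, 256, self.GRID.dims).astype(np.uint8),
                         value_kind="normalized8")

    def test_threshold_zero_sets_everything(self):
        out = va.binarize(self._vol(), 0)
        assert out.data.all()

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(va.DataError):
            va.binarize(self._vol(), 256)

    def test_matches_comparison_oracle(self):
        vol = self._vol()
        out = va.binarize(vol, 100)
        np.testing.assert_array_equal(out.data, (vol.data >= 100).astype(np.uint8))


class TestDownsample:
    def test_single_set_voxel_gives_single_cell(self):
        grid = va.VoxelGrid((16, 16, 16), (1, 1, 1))
        data = np.zeros(grid.dims, dtype=np.uint8)
        data[9, 2, 14] = 1
        out = va.downsample_mask(va.Volume(grid, data, value_kind="binary"), 4)
        assert out.data.sum() == 1
        assert out.data[2, 0, 3] == 1

    def test_empty_stays_empty(self):
        grid = va.VoxelGrid((16, 16, 16), (1, 1, 1))
        out = va.downsample_mask(
            va.Volume(grid, np.zeros(grid.dims, dtype=np.uint8), value_kind="binary"), 4)
        assert not out.data.any()

    def test_matches_any_reduction_oracle_on_ragged_grid(self):
        grid = va.VoxelGrid((37, 22, 15), (1, 1, 1))
        rng = np.random.default_rng(9)
        data = (rng.random(grid.dims) < 0.05).astype(np.uint8)
        out = va.downsample_mask(va.Volume(grid, data, value_kind="binary"), 4)
        assert out.grid.dims == (10, 6, 4)
        for cx in range(10):
            for cy in range(6):
                for cz in range(4):
                    cell = data[cx * 4:(cx + 1) * 4, cy * 4:(cy + 1) * 4,
                                cz * 4:(cz + 1) * 4]
                    assert out.data[cx, cy, cz] == int(cell.any())

    def test_factor_below_one_rejected(self):
        grid = va.VoxelGrid((8, 8, 8), (1, 1, 1))
        with pytest.raises(va.DataError):
            va.downsample_mask(va.Volume(grid, np.zeros(grid.dims, dtype=int),
                                         value_kind="binary"), 0)


def _random_masks(grid, n_lines, seed, density=0.02, factor=4):
    rng = np.random.default_rng(seed)
    records, masks = [], {}
    for i in range(n_lines):
        lid = f"t{i:03d}"
        records.append(va.LineRecord(lid, "Gal4", cell_threshold=1))
        data = (rng.random(grid.dims) < density).astype(np.uint8)
        masks[lid] = va.downsample_mask(
            va.Volume(grid, data, value_kind="binary"), factor, source_line=lid)
    registry = va.AtlasRegistry(grid, records)
    return registry, masks


class TestFragments:
    def test_264_line_fragment_is_about_17kb(self):
        grid = va.VoxelGrid((32, 16, 16), (1, 1, 1))
        registry, masks = _random_masks(grid, 264, seed=10)
        store = va.build_fragments(registry, masks)
        assert store.fragment_nbytes == 16_896
        assert all(len(f) == 16_896 for f in store.fragments.values())

    def test_single_line_fragments_are_64_bytes(self):
        grid = va.VoxelGrid((32, 16, 16), (1, 1, 1))
        registry, masks = _random_masks(grid, 1, seed=11)
        store = va.build_fragments(registry, masks)
        assert store.fragment_nbytes == 64

    def test_unpacking_fragment_slots_reproduces_inputs(self):
        grid = va.VoxelGrid((40, 24, 24), (1, 1, 1))
        registry, masks = _random_masks(grid, 5, seed=12, density=0.1)
        store = va.build_fragments(registry, masks)
        down = masks[registry.line_order[0]].grid.dims
        padded_dims = tuple(b * 8 for b in store.block_dims)
        for li, lid in enumerate(registry.line_order):
            full = np.pad(masks[lid].data,
                          [(0, p - d) for p, d in zip(padded_dims, down)])
            for coord in store.fragments:
                bx, by, bz = coord
                block = store.line_block(coord, li)
                np.testing.assert_array_equal(
                    block,
                    full[bx * 8:(bx + 1) * 8, by * 8:(by + 1) * 8,
                         bz * 8:(bz + 1) * 8],
                )

    def test_total_size_conservation(self):
        grid = va.VoxelGrid((32, 16, 16), (1, 1, 1))
        registry, masks = _random_masks(grid, 7, seed=13)
        store = va.build_fragments(registry, masks)
        n_blocks = int(np.prod(store.block_dims))
        assert store.total_nbytes == 64 * n_blocks * len(registry)

    def test_missing_line_rejected(self):
        grid = va.VoxelGrid((32, 16, 16), (1, 1, 1))
        registry, masks = _random_masks(grid, 3, seed=14)
        del masks[registry.line_order[1]]
        with pytest.raises(va.DataError, match="missing"):
            va.build_fragments(registry, masks)

    def test_store_round_trip_through_directory(self, tmp_path):
        grid = va.VoxelGrid((32, 16, 16), (1, 1, 1))
        registry, masks = _random_masks(grid, 4, seed=15)
        store = va.build_fragments(registry, masks)
        store.save(tmp_path / "idx")
        back = va.FragmentStore.load(tmp_path / "idx")
        assert back.line_order == store.line_order
        assert back.fragments == store.fragments
        assert back.down_dims == store.down_dims


class TestSpatialSearch:
    GRID = va.VoxelGrid((64, 32, 32), (1, 1, 1))

    def _setup(self, n_lines=20, seed=16, density=0.01):
        registry, masks = _random_masks(self.GRID, n_lines, seed, density=density)
        return registry, masks, va.build_fragments(registry, masks)

    def test_whole_grid_box_returns_lines_with_any_cell(self):
        registry, masks, store = self._setup()
        box = va.SearchBox((0, 0, 0), self.GRID.dims)
        hits = va.spatial_search(store, box, 1)
        expected = [lid for lid in registry.line_order if masks[lid].data.any()]
        assert hits == expected

    def test_empty_masks_return_nothing(self):
        registry, masks = _random_masks(self.GRID, 4, seed=17, density=0.0)
        store = va.build_fragments(registry, masks)
        assert va.spatial_search(store, va.SearchBox((0, 0, 0), self.GRID.dims)) == []

    def test_agrees_with_brute_force_on_random_boxes(self):
        registry, masks, store = self._setup()
        rng = np.random.default_rng(18)
        dims = np.array(self.GRID.dims)
        for _ in range(50):
            lo = np.array([rng.integers(0, d) for d in dims])
            hi = np.minimum(lo + rng.integers(1, 24, size=3), dims)
            box = va.SearchBox(tuple(lo), tuple(hi))
            min_cells = int(rng.integers(1, 6))
            assert va.spatial_search(store, box, min_cells) == \
                va.brute_force_search(masks, box, min_cells)

    def test_no_false_negatives_from_downsampling(self):
        # a set full-resolution voxel inside the box implies its line is found
        data = np.zeros(self.GRID.dims, dtype=np.uint8)
        data[13, 9, 21] = 1
        registry = va.AtlasRegistry(self.GRID, [va.LineRecord("solo", "Cre",
                                                              cell_threshold=1)])
        mask = va.downsample_mask(va.Volume(self.GRID, data, value_kind="binary"),
                                  4, source_line="solo")
        store = va.build_fragments(registry, {"solo": mask})
        box = va.SearchBox((13, 9, 21), (14, 10, 22))  # single-voxel box
        assert va.spatial_search(store, box, 1) == ["solo"]

    def test_min_cells_larger_than_box_returns_nothing(self):
        registry, masks, store = self._setup(n_lines=3, density=1.0)
        box = va.SearchBox((0, 0, 0), (4, 4, 4))  # one downsampled cell
        assert va.brute_force_search(masks, box, min_cells=2) == []

    def test_empty_converted_box_rejected(self):
        _, _, store = self._setup(n_lines=1)
        with pytest.raises(va.DataError):
            va.spatial_search(store, va.SearchBox((64, 32, 32), (64, 32, 32)))
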