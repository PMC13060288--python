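import numpy as np
import pandas as pd
import pytest
import tifffile
from hypothesis import given, settings, strategies as st

import smibridge as sb
from smibridge.errors import ValidationError
from conftest import naive_dense_stitch


def positions_df(coords):
    return pd.DataFrame(
        [(i + 1, x, y) for i, (x, y) in enumerate(coords)], columns=["fov", "x", "y"]
    )


class TestBounds:
    def test_single_tile_at_origin(self):
        b = sb.compute_global_bounds(positions_df([(0, 0)]), sb.TileShape(4256, 4256))
        assert (b.x_min, b.y_min, b.x_max, b.y_max) == (0, 0, 4256, 4256)

    def test_2x2_grid_canvas_is_8512(self):
        pos = positions_df([(0, 0), (4256, 0), (0, 4256), (4256, 4256)])
        b = sb.compute_global_bounds(pos, sb.TileShape(4256, 4256))
        assert (b.width, b.height) == (8512, 8512)

    def test_offset_grid_origin_and_extent(self):
        pos = positions_df([(100, 50), (300, 50)])
        b = sb.compute_global_bounds(pos, sb.TileShape(200, 200))
        assert (b.x_min, b.y_min) == (100, 50)
        assert (b.width, b.height) == (400, 200)

    @given(
        st.lists(
            st.tuples(
                st.floats(-1e6, 1e6, allow_nan=False),
                st.floats(-1e6, 1e6, allow_nan=False),
            ),
            min_size=1,
            max_size=8,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_bounds_contain_every_tile_corner(self, coords):
        tile = sb.TileShape(64, 48)
        b = sb.compute_global_bounds(positions_df(coords), tile)
        # brute force over all corners
        for x, y in coords:
            assert b.x_min <= x and x + tile.width <= b.x_max
            assert b.y_min <= y and y + tile.height <= b.y_max

    def test_empty_positions_rejected(self):
        with pytest.raises(ValidationError):
            sb.compute_global_bounds(positions_df([]), sb.TileShape(64, 64))


class TestOffsets:
    def test_single_fov_offset_is_zero(self):
        pos = positions_df([(12345.0, -77.0)])
        off = sb.assign_tile_offsets(pos, sb.compute_global_bounds(pos, sb.TileShape(64, 64)))
        assert off[["x_offset", "y_offset"]].to_numpy().tolist() == [[0, 0]]

    def test_2x2_grid_offsets(self):
        pos = positions_df([(0, 0), (4256, 0), (0, 4256), (4256, 4256)])
        off = sb.assign_tile_offsets(pos, sb.compute_global_bounds(pos, sb.TileShape(4256, 4256)))
        assert off[["x_offset", "y_offset"]].to_numpy().tolist() == [
            [0, 0], [4256, 0], [0, 4256], [4256, 4256],
        ]

    @given(st.floats(-5e5, 5e5, allow_nan=False), st.floats(-5e5, 5e5, allow_nan=False))
    @settings(deadline=None, max_examples=50)
    def test_translation_invariance(self, dx, dy):
        tile = sb.TileShape(64, 64)
        base = positions_df([(0, 0), (64, 0), (10.4, 70.6)])
        shifted = base.assign(x=base["x"] + dx, y=base["y"] + dy)
        a = sb.assign_tile_offsets(base, sb.compute_global_bounds(base, tile))
        b = sb.assign_tile_offsets(shifted, sb.compute_global_bounds(shifted, tile))
        pd.testing.assert_frame_equal(a, b)


class TestDownsample:
    def test_factor_one_is_identity(self):
        img = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(sb.downsample_image(img, 1), img)

    @pytest.mark.parametrize("factor", [2, 3, 7])
    def test_constant_image_stays_constant(self, factor):
        img = np.full((13, 9), 42.0)
        out = sb.downsample_image(img, factor)
        assert np.allclose(out, 42.0)
        assert out.shape == (-(-13 // factor), -(-9 // factor))

    def test_ramp_blocks_equal_explicit_means(self):
        img = np.arange(40.0 * 40).reshape(40, 40)
        out = sb.downsample_image(img, 20)
        expected = np.array(
            [
                [img[a : a + 20, b : b + 20].mean() for b in (0, 20)]
                for a in (0, 20)
            ]
        )
        assert np.array_equal(out, expected)

    @pytest.mark.parametrize("factor", [1, 2, 5, 20])
    def test_output_dims_are_ceil(self, factor):
        img = np.zeros((103, 57))
        out = sb.downsample_image(img, factor)
        assert out.shape == (-(-103 // factor), -(-57 // factor))

    def test_edge_blocks_average_only_present_pixels(self):
        img = np.ones((5, 5))
        img[4, :] = 11.0  # last single-row block
        out = sb.downsample_image(img, 4)
        assert out[1, 0] == 11.0  # not diluted by padding

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValidationError):
            sb.downsample_image(np.zeros((4, 4)), 0)


def make_tiles(values, shape=(64, 64), dtype=np.uint16):
    return {i + 1: np.full(shape, v, dtype=dtype) for i, v in enumerate(values)}


class TestStitchTiles:
    def test_single_constant_tile(self, tmp_path):
        tiles = make_tiles([7])
        pos = positions_df([(0, 0)])
        res = sb.stitch_tiles(tiles.__getitem__, pos, tmp_path)
        canvas = tifffile.imread(str(res.full_image))
        assert np.all(canvas == 7)

    @pytest.mark.parametrize("rows,cols", [(1, 2), (2, 2), (3, 3)])
    def test_grids_match_naive_dense_oracle(self, tmp_path, rows, cols):
        rng = np.random.default_rng(rows * 10 + cols)
        n = rows * cols
        tiles = {
            i + 1: rng.integers(0, 2**16, (64, 64), dtype=np.uint16)
            for i in range(n)
        }
        coords = [(c * 64, r * 64) for r in range(rows) for c in range(cols)]
        pos = positions_df(coords)
        res = sb.stitch_tiles(tiles.__getitem__, pos, tmp_path / f"{rows}x{cols}")
        canvas = tifffile.imread(str(res.full_image))
        expected = naive_dense_stitch(
            tiles, {i + 1: coords[i] for i in range(n)}, 64, 64
        )
        assert np.array_equal(canvas, expected)

    def test_overlapping_pair_larger_fov_wins(self, tmp_path):
        tiles = make_tiles([100, 200])
        pos = positions_df([(0, 0), (32, 0)])  # 32-px overlap
        res = sb.stitch_tiles(tiles.__getitem__, pos, tmp_path)
        canvas = tifffile.imread(str(res.full_image))
        expected = naive_dense_stitch(tiles, {1: (0, 0), 2: (32, 0)}, 64, 64)
        assert np.array_equal(canvas, expected)
        assert np.all(canvas[:, 32:64] == 200)  # contested region

    @pytest.mark.parametrize("batch_size", [1, 2, 3, 100])
    def test_batch_size_does_not_change_canvas(self, tmp_path, batch_size):
        rng = np.random.default_rng(3)
        tiles = {i + 1: rng.integers(0, 2**16, (64, 64), dtype=np.uint16) for i in range(4)}
        pos = positions_df([(0, 0), (64, 0), (0, 64), (64, 64)])
        ref = sb.stitch_tiles(tiles.__getitem__, pos, tmp_path / "ref", batch_size=4)
        out = sb.stitch_tiles(
            tiles.__getitem__, pos, tmp_path / f"b{batch_size}", batch_size=batch_size
        )
        assert np.array_equal(
            tifffile.imread(str(ref.full_image)), tifffile.imread(str(out.full_image))
        )

    def test_translation_leaves_canvas_and_offsets_unchanged(self, tmp_path):
        tiles = make_tiles([5, 9])
        base = positions_df([(0, 0), (64, 0)])
        shifted = base.assign(x=base["x"] + 1000, y=base["y"] - 500)
        a = sb.stitch_tiles(tiles.__getitem__, base, tmp_path / "a")
        b = sb.stitch_tiles(tiles.__getitem__, shifted, tmp_path / "b")
        assert np.array_equal(
            tifffile.imread(str(a.full_image)), tifffile.imread(str(b.full_image))
        )
        pd.testing.assert_frame_equal(a.positions, b.positions)

    def test_multichannel_tiles_preserved_verbatim(self, tmp_path):
        rng = np.random.default_rng(5)
        tiles = {1: rng.integers(0, 2**16, (3, 32, 32), dtype=np.uint16)}
        pos = positions_df([(0, 0)])
        res = sb.stitch_tiles(tiles.__getitem__, pos, tmp_path)
        assert np.array_equal(tifffile.imread(str(res.full_image)), tiles[1])

    def test_overview_dims_and_factor(self, tmp_path):
        tiles = make_tiles([1, 2, 3, 4], shape=(100, 100))
        pos = positions_df([(0, 0), (100, 0), (0, 100), (100, 100)])
        res = sb.stitch_tiles(tiles.__getitem__, pos, tmp_path, factor=20)
        ov = tifffile.imread(str(res.overview))
        assert res.factor == 20
        assert ov.shape == (10, 10)  # ceil(200 / 20)

    def test_overview_equals_blockmean_of_canvas(self, tmp_path):
        rng = np.random.default_rng(11)
        tiles = {1: rng.integers(0, 2**16, (70, 70), dtype=np.uint16)}
        res = sb.stitch_tiles(tiles.__getitem__, positions_df([(0, 0)]), tmp_path, factor=20)
        canvas = tifffile.imread(str(res.full_image))
        ov = tifffile.imread(str(res.overview))
        expected = np.rint(sb.downsample_image(canvas, 20)).astype(np.uint16)
        assert np.array_equal(ov, expected)

    def test_missing_tile_error_names_fov(self, tmp_path):
        tiles = make_tiles([1])
        pos = positions_df([(0, 0), (64, 0)])
        with pytest.raises(KeyError, match="2"):
            sb.stitch_tiles(tiles.__getitem__, pos, tmp_path)

    def test_tile_shape_mismatch_rejected(self, tmp_path):
        tiles = {1: np.zeros((64, 64), np.uint16), 2: np.zeros((32, 32), np.uint16)}
        pos = positions_df([(0, 0), (64, 0)])
        with pytest.raises(ValidationError, match="mismatch"):
            sb.stitch_tiles(tiles.__getitem__, pos, tmp_path)

    def test_post_stitch_csv_written_and_zero_based(self, tmp_path):
        tiles = make_tiles([1, 2])
        pos = positions_df([(500, 700), (564, 700)])
        res = sb.stitch_tiles(tiles.__getitem__, pos, tmp_path)
        back = sb.read_post_stitch_positions(res.positions_csv)
        assert back["x_offset"].min() == 0 and back["y_offset"].min() == 0
        pd.testing.assert_frame_equal(back, res.positions)


class TestTileDirectorySource:
    def test_resolves_default_pattern(self, small_export):
        _, paths = small_export
        src = sb.TileDirectorySource(paths.directory)
        arr = src(1)
        assert arr.shape == (2, 256, 256)

    def test_missing_fov_raises(self, small_export):
        _, paths = small_export
        src = sb.TileDirectorySource(paths.directory)
        with pytest.raises(FileNotFoundError, match="99"):
            src(99)
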