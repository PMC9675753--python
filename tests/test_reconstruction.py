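"""Trim rules, mask placement, nested resolution and exactly-once coverage."""

import numpy as np
import pytest

from myofiberquant.backends import SegmentationParams, oracle_backend, segment_tile
from myofiberquant.errors import ConsistencyError
from myofiberquant.imaging import LabelImage, TileName
from myofiberquant.reconstruction import (
    PlacedMask,
    TrimContext,
    place_tiles,
    rasterize_wsi,
    reconstruct_wsi,
    resolve_nested,
    trim_context_for,
    trim_tile_masks,
)
from myofiberquant.tiling import BoundingBox, extract_tile, make_tiles


def _tile_with_mask(rows, cols, h=712, w=712, lab=1):
    arr = np.zeros((h, w), dtype=np.int32)
    arr[rows[0] : rows[1], cols[0] : cols[1]] = lab
    return LabelImage(arr)


ALL_NEIGHBORS = TrimContext(overlap_px=200)


class TestTrimRules:
    def test_mask_inside_top_stripe_removed(self):
        # rows 50..149: entirely above row 200, never reaches row 199
        out = trim_tile_masks(_tile_with_mask((50, 150), (300, 400)), ALL_NEIGHBORS)
        assert out.label_values().size == 0

    def test_mask_reaching_keep_band_kept(self):
        # rows 150..249 include row 199 (the keep band) -> kept
        out = trim_tile_masks(_tile_with_mask((150, 250), (300, 400)), ALL_NEIGHBORS)
        assert set(out.label_values()) == {1}

    def test_mask_ending_exactly_at_row_198_removed(self):
        out = trim_tile_masks(_tile_with_mask((100, 199), (300, 400)), ALL_NEIGHBORS)
        assert out.label_values().size == 0

    def test_mask_ending_exactly_at_row_199_kept(self):
        out = trim_tile_masks(_tile_with_mask((100, 200), (300, 400)), ALL_NEIGHBORS)
        assert set(out.label_values()) == {1}

    def test_left_stripe_symmetric(self):
        out = trim_tile_masks(_tile_with_mask((300, 400), (50, 150)), ALL_NEIGHBORS)
        assert out.label_values().size == 0

    def test_mask_touching_bottom_removed(self):
        out = trim_tile_masks(_tile_with_mask((600, 712), (300, 400)), ALL_NEIGHBORS)
        assert out.label_values().size == 0

    def test_mask_touching_right_removed(self):
        out = trim_tile_masks(_tile_with_mask((300, 400), (600, 712)), ALL_NEIGHBORS)
        assert out.label_values().size == 0

    def test_mask_one_pixel_from_bottom_kept(self):
        out = trim_tile_masks(_tile_with_mask((600, 711), (300, 400)), ALL_NEIGHBORS)
        assert set(out.label_values()) == {1}

    def test_rules_suppressed_without_neighbors(self):
        ctx = TrimContext(
            overlap_px=200,
            has_left_neighbor=False,
            has_top_neighbor=False,
            has_right_neighbor=False,
            has_bottom_neighbor=False,
        )
        for rows, cols in [((50, 150), (300, 400)), ((600, 712), (300, 400)),
                           ((300, 400), (50, 150)), ((300, 400), (600, 712))]:
            out = trim_tile_masks(_tile_with_mask(rows, cols), ctx)
            assert set(out.label_values()) == {1}

    def test_untouched_masks_pixel_identical(self):
        img = _tile_with_mask((250, 350), (250, 350))
        out = trim_tile_masks(img, ALL_NEIGHBORS)
        assert out == img

    def test_trim_context_for_edges(self):
        grid = make_tiles(BoundingBox(0, 0, 1224, 1224))
        top_left = trim_context_for(grid.tile_at(0, 0), grid)
        assert not top_left.has_top_neighbor and not top_left.has_left_neighbor
        assert top_left.has_bottom_neighbor and top_left.has_right_neighbor
        bottom_right = trim_context_for(grid.tile_at(512, 512), grid)
        assert bottom_right.has_top_neighbor and bottom_right.has_left_neighbor
        assert not bottom_right.has_bottom_neighbor and not bottom_right.has_right_neighbor


class TestPlacement:
    def test_offsets_and_fresh_labels(self):
        grid = make_tiles(BoundingBox(0, 0, 1224, 712))
        t0 = _tile_with_mask((10, 20), (10, 20), lab=7)
        t1 = _tile_with_mask((30, 40), (30, 40), lab=7)
        placed = place_tiles(
            [(t1, TileName("s", 512, 0)), (t0, TileName("s", 0, 0))], grid
        )
        assert [m.global_label for m in placed] == [1, 2]
        # deterministic (y0, x0) tile order regardless of input order
        assert placed[0].source_tile.x0 == 0
        assert (placed[0].x0, placed[0].y0) == (10, 10)
        assert (placed[1].x0, placed[1].y0) == (512 + 30, 30)
        assert placed[1].area_px == 100

    def test_shape_mismatch_rejected(self):
        grid = make_tiles(BoundingBox(0, 0, 1224, 712))
        bad = LabelImage(np.zeros((10, 10), dtype=np.int32))
        with pytest.raises(ConsistencyError):
            place_tiles([(bad, TileName("s", 0, 0))], grid)

    def test_unknown_tile_origin_rejected(self):
        grid = make_tiles(BoundingBox(0, 0, 712, 712))
        t = _tile_with_mask((0, 5), (0, 5))
        with pytest.raises(ConsistencyError):
            place_tiles([(t, TileName("s", 3, 3))], grid)


def _placed(label, x0, y0, patch):
    return PlacedMask(label, TileName("s", 0, 0), x0, y0, np.asarray(patch, bool))


class TestResolveNested:
    def test_contained_smaller_removed(self):
        big = _placed(1, 0, 0, np.ones((10, 10)))
        small = _placed(2, 2, 2, np.ones((4, 4)))
        out = resolve_nested([big, small])
        assert [m.global_label for m in out] == [1]

    def test_disjoint_kept(self):
        a = _placed(1, 0, 0, np.ones((5, 5)))
        b = _placed(2, 20, 20, np.ones((5, 5)))
        assert len(resolve_nested([a, b])) == 2

    def test_partial_overlap_below_containment_kept(self):
        a = _placed(1, 0, 0, np.ones((10, 10)))
        b = _placed(2, 5, 0, np.ones((10, 10)))  # 50% of b inside a
        assert len(resolve_nested([a, b])) == 2

    def test_containment_at_95_percent(self):
        a = _placed(1, 0, 0, np.ones((20, 20)))
        # b: 100 px, 95 inside a, 5 outside
        patch = np.ones((5, 20), dtype=bool)
        b = _placed(2, 1, 16, patch)  # sticks out below and to the right of a
        # intersection = 4 rows * 19 cols = 76 < 0.95 * 100 -> kept
        assert len(resolve_nested([a, b])) == 2
        # c: fully inside a -> removed
        patchc = np.ones((10, 10), dtype=bool)
        patchc[0, :5] = False  # 95 px
        c = _placed(3, 5, 5, patchc)
        out = resolve_nested([a, c])
        assert [m.global_label for m in out] == [1]

    def test_identical_duplicates_keep_lower_label(self):
        a = _placed(4, 3, 3, np.ones((6, 6)))
        b = _placed(9, 3, 3, np.ones((6, 6)))
        out = resolve_nested([b, a])
        assert [m.global_label for m in out] == [4]

    def test_empty_input(self):
        assert resolve_nested([]) == []


class TestRasterize:
    def test_contested_pixels_go_to_larger(self):
        big = _placed(1, 0, 0, np.ones((10, 10)))
        small = _placed(2, 8, 0, np.ones((4, 4)))
        out = rasterize_wsi([small, big], (20, 20))
        # overlap columns 8..9 of rows 0..3 belong to the larger mask
        assert (out.labels[0:4, 8:10] == 1).all()
        assert (out.labels[0:4, 10:12] == 2).all()

    def test_area_conserved_without_overlap(self):
        a = _placed(1, 0, 0, np.ones((5, 5)))
        b = _placed(2, 10, 10, np.ones((3, 3)))
        out = rasterize_wsi([a, b], (20, 20))
        assert out.areas() == {1: 25, 2: 9}


class TestExactlyOnce:
    def test_oracle_reconstruction_is_lossless(self, clean_scene):
        """Tile with overlap, segment with the oracle, reconstruct: the result
        must equal the ground truth up to label permutation (every fiber
        recovered exactly once with identical pixels)."""
        h, w = clean_scene.image.shape
        grid = make_tiles(BoundingBox(0, 0, w, h))
        assert len(grid) == 4  # 1024 -> origins {0, 312} in both axes
        backend = oracle_backend(clean_scene)
        tile_labels = []
        for t in grid:
            tile = extract_tile(clean_scene.image, t)
            out = segment_tile(backend, tile, SegmentationParams())
            tile_labels.append((out, TileName("s", t.x0, t.y0)))
        recon, placed = reconstruct_wsi(tile_labels, grid, (h, w))

        gt = clean_scene.gt_fibers
        assert len(placed) == len(gt.label_values())
        # pixel-identical up to label permutation: foreground matches and
        # every gt label maps to exactly one recon label and vice versa
        assert ((recon.labels > 0) == (gt.labels > 0)).all()
        fg = gt.labels > 0
        pairs = set(zip(gt.labels[fg].tolist(), recon.labels[fg].tolist()))
        assert len(pairs) == len(gt.label_values())

    def test_reconstruction_invariant_to_tile_order(self, clean_scene):
        h, w = clean_scene.image.shape
        grid = make_tiles(BoundingBox(0, 0, w, h))
        backend = oracle_backend(clean_scene)
        tile_labels = []
        for t in grid:
            tile = extract_tile(clean_scene.image, t)
            tile_labels.append(
                (segment_tile(backend, tile, SegmentationParams()), TileName("s", t.x0, t.y0))
            )
        r1, _ = reconstruct_wsi(tile_labels, grid, (h, w))
        r2, _ = reconstruct_wsi(list(reversed(tile_labels)), grid, (h, w))
        assert r1 == r2
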