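"""Whole-slide mask reconstruction from overlapped tile segmentations.

Each tile is segmented independently, so a fiber in the shared strip of two
tiles appears (possibly cut) in both. Reconstruction makes each fiber
survive in exactly one tile:

* stripe rule — masks lying entirely in the top/left overlap stripe of a
  tile are removed (that copy belongs to the neighbor), except masks
  reaching the stripe's inner edge, which are kept;
* border rule — masks cut by the right/bottom tile border are removed
  (the neighbor sees them whole);
* surviving masks are placed at their global position (decoded from the
  tile name), and residual nested duplicates are resolved by keeping the
  larger mask.

Both rules are suppressed at the slide edge (no neighbor on that side), so
genuine tissue-edge fibers are not discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy import ndimage

from .errors import ConsistencyError, ExtentError
from .imaging import LabelImage, TileName, mask_to_polygon
from .tiling import TileGrid, TileSpec

__all__ = [
    "TrimContext",
    "PlacedMask",
    "trim_tile_masks",
    "trim_context_for",
    "place_tiles",
    "resolve_nested",
    "rasterize_wsi",
    "reconstruct_wsi",
]


@dataclass
class TrimContext:
    """Which neighbors a tile has, and the grid overlap, for trimming."""

    overlap_px: int
    has_left_neighbor: bool = True
    has_top_neighbor: bool = True
    has_right_neighbor: bool = True
    has_bottom_neighbor: bool = True


@dataclass
class PlacedMask:
    """One surviving tile mask placed in WSI coordinates.

    The raster patch is the source of truth (pixel-exact); the polygon is
    derived lazily for vector export.
    """

    global_label: int
    source_tile: TileName
    x0: int  # global bbox origin (columns)
    y0: int  # global bbox origin (rows)
    patch: np.ndarray  # bool array of shape (bbox_h, bbox_w)

    @property
    def area_px(self) -> int:
        return int(self.patch.sum())

    @property
    def bounds(self) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1), half-open."""
        return (self.x0, self.y0, self.x0 + self.patch.shape[1], self.y0 + self.patch.shape[0])

    @cached_property
    def polygon(self):
        return mask_to_polygon(self.patch, x_off=self.x0, y_off=self.y0)


def trim_context_for(tile: TileSpec, grid: TileGrid) -> TrimContext:
    """Neighbor flags for a tile of a grid (edge tiles lack neighbors)."""
    return TrimContext(
        overlap_px=grid.params.overlap_px,
        has_left_neighbor=tile.col_index > 0,
        has_top_neighbor=tile.row_index > 0,
        has_right_neighbor=tile.col_index < grid.n_cols - 1,
        has_bottom_neighbor=tile.row_index < grid.n_rows - 1,
    )


def trim_tile_masks(tile_labels: LabelImage, ctx: TrimContext) -> LabelImage:
    """Apply the stripe and border removal rules to one tile's masks.

    Stripe rule (top/left, only with a neighbor on that side): a mask whose
    pixels all lie above row ``overlap`` is removed unless it reaches row
    ``overlap - 1``; this one-pixel keep band makes the
    removed-from-one-side/kept-on-the-other split exhaustive, so every
    fiber survives in exactly one tile. Symmetric for columns.

    Border rule (bottom/right, only with a neighbor): masks touching the
    last row/column are removed — the neighbor tile sees them whole.
    """
    labels = tile_labels.labels.copy()
    h, w = labels.shape
    ov = ctx.overlap_px
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        rmin, rmax = sl[0].start, sl[0].stop - 1
        cmin, cmax = sl[1].start, sl[1].stop - 1
        remove = False
        if ctx.has_top_neighbor and rmax < ov - 1:
            remove = True
        if ctx.has_left_neighbor and cmax < ov - 1:
            remove = True
        if ctx.has_bottom_neighbor and rmax == h - 1:
            remove = True
        if ctx.has_right_neighbor and cmax == w - 1:
            remove = True
        if remove:
            sub = labels[sl]
            sub[sub == lab] = 0
    return LabelImage(labels)


def place_tiles(
    trimmed: list[tuple[LabelImage, TileName]], grid: TileGrid
) -> list[PlacedMask]:
    """Offset every surviving tile mask to WSI coordinates with fresh labels.

    Tiles are processed in (y0, x0) order regardless of input order, so the
    global labeling is deterministic.
    """
    placed: list[PlacedMask] = []
    next_label = 1
    for labels, name in sorted(trimmed, key=lambda p: (p[1].y0, p[1].x0, p[1].slide_id)):
        tile = grid.tile_at(name.x0, name.y0)  # raises ConsistencyError if absent
        if labels.shape != (tile.height, tile.width):
            raise ConsistencyError(
                f"tile {name} label shape {labels.shape} does not match grid tile "
                f"({tile.height}, {tile.width})"
            )
        slices = ndimage.find_objects(labels.labels)
        for lab, sl in enumerate(slices, start=1):
            if sl is None:
                continue
            patch = labels.labels[sl] == lab
            placed.append(
                PlacedMask(
                    global_label=next_label,
                    source_tile=name,
                    x0=name.x0 + sl[1].start,
                    y0=name.y0 + sl[0].start,
                    patch=patch,
                )
            )
            next_label += 1
    return placed


def _pixel_intersection(a: PlacedMask, b: PlacedMask) -> int:
    ax0, ay0, ax1, ay1 = a.bounds
    bx0, by0, bx1, by1 = b.bounds
    x0, x1 = max(ax0, bx0), min(ax1, bx1)
    y0, y1 = max(ay0, by0), min(ay1, by1)
    if x0 >= x1 or y0 >= y1:
        return 0
    pa = a.patch[y0 - ay0 : y1 - ay0, x0 - ax0 : x1 - ax0]
    pb = b.patch[y0 - by0 : y1 - by0, x0 - bx0 : x1 - bx0]
    return int(np.logical_and(pa, pb).sum())


def resolve_nested(
    masks: list[PlacedMask], containment: float = 0.95
) -> list[PlacedMask]:
    """Remove nested duplicate masks, keeping the larger of each pair.

    Two masks are "nested" when their intersection covers at least
    ``containment`` of the smaller mask's area; the smaller is dropped
    (ties broken by keeping the lower global label). Residual partial
    overlaps are left for rasterization, where contested pixels go to the
    larger mask.
    """
    if not masks:
        return []
    order = sorted(masks, key=lambda m: m.global_label)
    bounds = np.array([m.bounds for m in order])
    areas = np.array([m.area_px for m in order])
    removed = np.zeros(len(order), dtype=bool)
    for i in range(len(order)):
        if removed[i]:
            continue
        # bbox-gated candidate pairs
        inter_x = np.minimum(bounds[:, 2], bounds[i, 2]) > np.maximum(bounds[:, 0], bounds[i, 0])
        inter_y = np.minimum(bounds[:, 3], bounds[i, 3]) > np.maximum(bounds[:, 1], bounds[i, 1])
        for j in np.nonzero(inter_x & inter_y)[0]:
            if j <= i or removed[j] or removed[i]:
                continue
            inter = _pixel_intersection(order[i], order[j])
            if inter == 0:
                continue
            small, big = (i, j) if areas[i] < areas[j] else (j, i)
            if areas[i] == areas[j]:
                # equal areas: keep the lower label
                small, big = max(i, j), min(i, j)
            if inter >= containment * areas[small]:
                removed[small] = True
    return [m for m, r in zip(order, removed) if not r]


def rasterize_wsi(masks: list[PlacedMask], wsi_shape: tuple[int, int]) -> LabelImage:
    """Paint placed masks into one WSI-sized label image.

    Masks are painted in increasing area order so that pixels contested by
    residual partial overlaps end up with the larger mask.
    """
    h, w = wsi_shape
    out = np.zeros((h, w), dtype=np.int32)
    for m in sorted(masks, key=lambda m: (m.area_px, m.global_label)):
        x0, y0, x1, y1 = m.bounds
        if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
            raise ExtentError(
                f"mask {m.global_label} bounds {m.bounds} outside WSI {w}x{h}"
            )
        region = out[y0:y1, x0:x1]
        region[m.patch] = m.global_label
    return LabelImage(out)


def reconstruct_wsi(
    tile_labels: list[tuple[LabelImage, TileName]],
    grid: TileGrid,
    wsi_shape: tuple[int, int],
) -> tuple[LabelImage, list[PlacedMask]]:
    """Full reconstruction: trim every tile, place, resolve nesting, rasterize."""
    trimmed = []
    for labels, name in tile_labels:
        tile = grid.tile_at(name.x0, name.y0)
        ctx = trim_context_for(tile, grid)
        trimmed.append((trim_tile_masks(labels, ctx), name))
    placed = place_tiles(trimmed, grid)
    resolved = resolve_nested(placed)
    return rasterize_wsi(resolved, wsi_shape), resolved
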