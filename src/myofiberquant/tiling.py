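"""Tissue detection and overlapped tile grids.

Whole-slide sections are first screened at low resolution for
tissue-bearing regions (bright H&E background vs darker stained tissue),
then each region's bounding box is divided into fixed-size tiles that
overlap enough that no fiber is cut by both limits of the shared strip.
Defaults follow the tuned workflow: 7 um/px working resolution, max-of-RGB
score thresholded at 190, 712 px tiles with 200 px overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ExtentError, ParameterError
from .imaging import CalibratedImage

__all__ = [
    "TissueParams",
    "TileParams",
    "TileSpec",
    "TileGrid",
    "BoundingBox",
    "detect_tissue",
    "make_tiles",
    "extract_tile",
]


@dataclass
class TissueParams:
    """Low-resolution tissue thresholder parameters.

    The score of a pixel is max(R, G, B) after resampling to
    ``work_resolution_um`` and optional Gaussian prefiltering. With
    ``tissue_below`` (the default), a pixel is tissue iff score < threshold:
    H&E background is near-white, so its max-channel is high.
    """

    work_resolution_um: float = 7.0
    gaussian_sigma: float = 0.0
    threshold: int = 190
    tissue_below: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ParameterError(f"threshold must be in [0, 255], got {self.threshold}")
        if self.gaussian_sigma < 0:
            raise ParameterError("gaussian_sigma must be >= 0")
        if self.work_resolution_um <= 0:
            raise ParameterError("work_resolution_um must be > 0")


@dataclass
class TileParams:
    """Tile size and overlap in full-resolution pixels."""

    tile_size_px: int = 712
    overlap_px: int = 200

    def __post_init__(self) -> None:
        if self.tile_size_px < 1:
            raise ParameterError("tile_size_px must be >= 1")
        if self.overlap_px < 0 or self.overlap_px >= self.tile_size_px:
            raise ParameterError(
                f"overlap_px must satisfy 0 <= overlap < tile size, got "
                f"{self.overlap_px} vs {self.tile_size_px}"
            )

    @property
    def step(self) -> int:
        return self.tile_size_px - self.overlap_px


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel extent [x0, x0+width) x [y0, y0+height)."""

    x0: int
    y0: int
    width: int
    height: int


@dataclass(frozen=True)
class TileSpec:
    x0: int
    y0: int
    width: int
    height: int
    row_index: int
    col_index: int


@dataclass
class TileGrid:
    tiles: list[TileSpec]
    region: BoundingBox
    params: TileParams

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self):
        return iter(self.tiles)

    def tile_at(self, x0: int, y0: int) -> TileSpec:
        for t in self.tiles:
            if t.x0 == x0 and t.y0 == y0:
                return t
        from .errors import ConsistencyError

        raise ConsistencyError(f"no tile with origin ({x0}, {y0}) in grid")

    @property
    def n_rows(self) -> int:
        return 1 + max(t.row_index for t in self.tiles)

    @property
    def n_cols(self) -> int:
        return 1 + max(t.col_index for t in self.tiles)


def _block_average(pixels: np.ndarray, factor: float) -> np.ndarray:
    """Anti-aliased downsampling by area averaging (per channel)."""
    from skimage.transform import resize

    h, w = pixels.shape[:2]
    out_h = max(1, int(round(h / factor)))
    out_w = max(1, int(round(w / factor)))
    return resize(
        pixels.astype(np.float64),
        (out_h, out_w, pixels.shape[2]),
        order=1,
        anti_aliasing=True,
        preserve_range=True,
    )


def detect_tissue(
    img: CalibratedImage, p: TissueParams | None = None
) -> tuple[np.ndarray, list[BoundingBox]]:
    """Detect tissue-bearing regions at low resolution.

    Returns the low-resolution binary tissue mask and the bounding boxes of
    its 4-connected components mapped back to full-resolution coordinates.
    """
    p = p or TissueParams()
    if p.work_resolution_um < img.pixel_size_um:
        raise ParameterError(
            f"work_resolution_um ({p.work_resolution_um}) must be >= native "
            f"pixel size ({img.pixel_size_um})"
        )
    factor = p.work_resolution_um / img.pixel_size_um
    low = _block_average(img.pixels, factor)
    if p.gaussian_sigma > 0:
        low = ndimage.gaussian_filter(low, sigma=(p.gaussian_sigma, p.gaussian_sigma, 0))
    score = low.max(axis=2)
    mask = score < p.threshold if p.tissue_below else score >= p.threshold

    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    comps, n = ndimage.label(mask, structure=structure)
    boxes: list[BoundingBox] = []
    h, w = img.shape
    # map low-res bbox back to full resolution via the effective scale
    sy = h / mask.shape[0]
    sx = w / mask.shape[1]
    for sl in ndimage.find_objects(comps):
        if sl is None:
            continue
        y0 = int(np.floor(sl[0].start * sy))
        y1 = min(int(np.ceil(sl[0].stop * sy)), h)
        x0 = int(np.floor(sl[1].start * sx))
        x1 = min(int(np.ceil(sl[1].stop * sx)), w)
        boxes.append(BoundingBox(x0, y0, x1 - x0, y1 - y0))
    return mask, boxes


def _axis_origins(extent: int, tile: int, step: int) -> list[int]:
    """Tile origins along one axis: regular steps, last tile shifted inward."""
    if extent <= tile:
        return [0]
    origins = list(range(0, extent - tile + 1, step))
    if origins[-1] + tile < extent:
        origins.append(extent - tile)
    return origins


def make_tiles(region: BoundingBox, p: TileParams | None = None) -> TileGrid:
    """Lay an overlapped tile grid over a region.

    Tiles start at the region origin with step = tile_size - overlap. The
    last row/column is shifted inward so every tile stays full-sized and
    in-bounds (giving it a larger overlap with its neighbor); if the region
    is smaller than one tile in an axis, a single region-sized tile spans
    that axis.
    """
    p = p or TileParams()
    if region.width < 1 or region.height < 1:
        raise ParameterError("region must have width and height >= 1")
    xs = _axis_origins(region.width, p.tile_size_px, p.step)
    ys = _axis_origins(region.height, p.tile_size_px, p.step)
    w = min(p.tile_size_px, region.width)
    h = min(p.tile_size_px, region.height)
    tiles = [
        TileSpec(region.x0 + x, region.y0 + y, w, h, ri, ci)
        for ri, y in enumerate(ys)
        for ci, x in enumerate(xs)
    ]
    return TileGrid(tiles, region, p)


def extract_tile(img: CalibratedImage, t: TileSpec) -> CalibratedImage:
    """Pixel-exact crop of a tile; calibration is propagated.

    The crop carries an ``origin`` attribute (x0, y0) so that
    origin-aware backends (e.g. the oracle) can place it without search.
    """
    crop = img.crop(t.x0, t.y0, t.width, t.height)
    crop.origin = (t.x0, t.y0)
    return crop
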