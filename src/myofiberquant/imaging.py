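"""Raster and vector I/O with the pipeline's coordinate conventions.

Conventions used everywhere in the package:

* x = column, y = row, origin at the top-left, 0-based.
* Extents are pixel-corner aligned and half-open: a tile at (x0, y0) with
  width w and height h covers columns [x0, x0+w) and rows [y0, y0+h).
* Label images are non-negative integer rasters; 0 is background and each
  positive value is one object (the mask-image convention of instance
  segmenters that emit "a PNG where pixels of the same cell share a value").
* GeoJSON coordinates are pixel units of the full-resolution image (the
  QuPath convention); physical calibration travels separately as
  ``pixel_size_um``.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage
from shapely.geometry import MultiPolygon, Polygon, box, mapping, shape as shapely_shape
from shapely.ops import unary_union
import shapely

from .errors import (
    CapacityError,
    DegenerateGeometryError,
    ExtentError,
    FormatError,
    ParameterError,
    ParseError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CalibratedImage",
    "LabelImage",
    "TileName",
    "Annotation",
    "AnnotationSet",
    "read_label_image",
    "write_label_image",
    "encode_tile_name",
    "decode_tile_name",
    "labels_to_polygons",
    "polygons_to_labels",
    "read_geojson",
    "write_geojson",
    "read_calibrated_tiff",
    "write_calibrated_tiff",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CalibratedImage:
    """An RGB raster together with its physical pixel size.

    Parameters
    ----------
    pixels : ndarray of shape (H, W, 3), uint8
        8-bit RGB image data.
    pixel_size_um : float
        Isotropic pixel size in micrometres per pixel. Every physical
        measurement downstream (diameters in um, distance thresholds)
        goes through this value.
    """

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError(
                f"expected an (H, W, 3) RGB array, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise FormatError("image must have height and width >= 1")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise FormatError("channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if not self.pixel_size_um > 0:
            raise ParameterError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        return self.pixels.shape[:2]

    def crop(self, x0: int, y0: int, width: int, height: int) -> "CalibratedImage":
        h, w = self.shape
        if x0 < 0 or y0 < 0 or x0 + width > w or y0 + height > h:
            raise ExtentError(
                f"crop [{x0},{x0 + width})x[{y0},{y0 + height}) exceeds image {w}x{h}"
            )
        return CalibratedImage(
            self.pixels[y0 : y0 + height, x0 : x0 + width].copy(), self.pixel_size_um
        )


@dataclass
class LabelImage:
    """Integer instance mask: 0 = background, each positive value one object."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError(f"label raster must be 2-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError(f"label raster must be integer, got dtype {self.labels.dtype}")
        if self.labels.size and self.labels.min() < 0:
            raise FormatError("labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def label_values(self) -> np.ndarray:
        """Sorted array of distinct positive labels present."""
        vals = np.unique(self.labels)
        return vals[vals > 0]

    def areas(self) -> dict[int, int]:
        """Pixel count per positive label."""
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts) if v > 0}

    def __eq__(self, other: object) -> bool:  # pixelwise equality
        if not isinstance(other, LabelImage):
            return NotImplemented
        return self.labels.shape == other.labels.shape and bool(
            np.array_equal(self.labels, other.labels)
        )


@dataclass(frozen=True)
class TileName:
    """Tile identity: slide id plus the tile's top-left origin in WSI pixels."""

    slide_id: str
    x0: int
    y0: int

    def __post_init__(self) -> None:
        if self.x0 < 0 or self.y0 < 0:
            raise ParameterError("tile origin coordinates must be >= 0")


@dataclass
class Annotation:
    """One closed polygon with a class label (QuPath 'classification')."""

    polygon: Polygon
    class_label: str = "unclassified"
    properties: dict = field(default_factory=dict)


@dataclass
class AnnotationSet:
    """A list of classed polygons in WSI pixel coordinates."""

    annotations: list[Annotation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations)

    def __getitem__(self, i):
        return self.annotations[i]

    def with_class(self, class_label: str) -> "AnnotationSet":
        return AnnotationSet([a for a in self.annotations if a.class_label == class_label])


# ---------------------------------------------------------------------------
# Label raster I/O (16-bit PNG)
# ---------------------------------------------------------------------------


def read_label_image(path) -> LabelImage:
    """Read an instance label raster from an 8- or 16-bit single-channel PNG/TIFF.

    Every distinct non-zero pixel value becomes a distinct label.
    """
    with Image.open(path) as im:
        if im.mode in ("RGB", "RGBA", "P"):
            raise FormatError(
                f"{path}: expected a single-channel integer raster, got mode {im.mode!r}"
            )
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2-D raster, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: expected integer pixels, got dtype {arr.dtype}")
    return LabelImage(arr.astype(np.int32))


def _enforce_connectivity(labels: np.ndarray) -> np.ndarray:
    """Relabel so each label is one 4-connected component (warn when splitting)."""
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    out = labels.copy()
    next_label = int(labels.max()) + 1 if labels.size else 1
    for lab in np.unique(labels):
        if lab <= 0:
            continue
        mask = labels == lab
        comps, n = ndimage.label(mask, structure=structure)
        if n > 1:
            logger.warning(
                "label %d has %d 4-connected components; relabeling extras", lab, n
            )
            for comp in range(2, n + 1):
                out[comps == comp] = next_label
                next_label += 1
    return out


def write_label_image(img: LabelImage, path) -> None:
    """Write a label image as 16-bit PNG.

    Labels with multiple 4-connected components are split into one label per
    component (with a logged warning), preserving the one-label-one-object
    reading of the mask convention.
    """
    maxlab = int(img.labels.max()) if img.labels.size else 0
    if maxlab > 65535:
        raise CapacityError(f"max label {maxlab} exceeds 16-bit PNG capacity (65535)")
    labels = _enforce_connectivity(img.labels)
    if int(labels.max()) > 65535:
        raise CapacityError("relabeling pushed labels past 16-bit capacity")
    Image.fromarray(labels.astype(np.uint16)).save(path, format="PNG")


# ---------------------------------------------------------------------------
# Tile-name codec
# ---------------------------------------------------------------------------

_TILE_NAME_RE = re.compile(r"^(?P<slide>.+)_x(?P<x>\d+)_y(?P<y>\d+)$")


def encode_tile_name(t: TileName, extension: str = ".tif") -> str:
    """Encode a tile's slide id and origin as ``{slide}_x{X}_y{Y}{ext}``."""
    return f"{t.slide_id}_x{t.x0}_y{t.y0}{extension}"


def decode_tile_name(s: str) -> TileName:
    """Invert :func:`encode_tile_name` (any extension is stripped)."""
    stem = s.rsplit("/", 1)[-1]
    if "." in stem:
        stem = stem[: stem.rindex(".")]
    m = _TILE_NAME_RE.match(stem)
    if m is None:
        raise ParseError(
            f"cannot parse tile name {s!r}: expected pattern '{{slide}}_x{{X}}_y{{Y}}.ext'"
        )
    return TileName(m.group("slide"), int(m.group("x")), int(m.group("y")))


# ---------------------------------------------------------------------------
# Label raster <-> polygons
# ---------------------------------------------------------------------------


def mask_to_polygon(mask: np.ndarray, x_off: float = 0.0, y_off: float = 0.0) -> Polygon:
    """Exact pixel-corner polygon of a boolean mask.

    Built as the union of one axis-aligned rectangle per row run, so the
    polygon's area equals the pixel count exactly. Returns the largest part
    if the mask is not connected. Holes are preserved in the polygon.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise DegenerateGeometryError("empty mask has no polygon")
    boxes = []
    for r in np.unique(rows):
        cs = np.sort(cols[rows == r])
        # split into consecutive runs
        breaks = np.nonzero(np.diff(cs) > 1)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [cs.size - 1]))
        for s, e in zip(starts, ends):
            boxes.append(box(cs[s] + x_off, r + y_off, cs[e] + 1 + x_off, r + 1 + y_off))
    geom = unary_union(boxes)
    if isinstance(geom, MultiPolygon):
        geom = max(geom.geoms, key=lambda g: g.area)
    return Polygon(
        geom.exterior.simplify(0, preserve_topology=False),
        [i.simplify(0, preserve_topology=False) for i in geom.interiors],
    )


def labels_to_polygons(img: LabelImage, class_label: str = "unclassified") -> AnnotationSet:
    """Vectorize every label into one exact outer polygon.

    Holes are recorded on the polygon but ignored by downstream area/IoU
    consumers that re-rasterize; each label yields exactly one polygon (its
    largest connected component if the invariant is violated).
    """
    anns: list[Annotation] = []
    slices = ndimage.find_objects(img.labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        sub = img.labels[sl] == lab
        poly = mask_to_polygon(sub, x_off=sl[1].start, y_off=sl[0].start)
        anns.append(Annotation(poly, class_label, {"label": lab}))
    return AnnotationSet(anns)


def rasterize_polygon_patch(poly: Polygon) -> tuple[np.ndarray, tuple[int, int]]:
    """Rasterize a polygon by pixel-center containment, bbox-sized.

    Returns (patch, (x0, y0)): a boolean array over the polygon's integer
    bounding box and that box's top-left pixel. A pixel (row y, col x) is
    inside iff the point (x+0.5, y+0.5) lies strictly within the polygon;
    for corner-aligned polygons this inverts :func:`mask_to_polygon`
    exactly.
    """
    minx, miny, maxx, maxy = poly.bounds
    c0, c1 = int(np.floor(minx)), int(np.ceil(maxx))
    r0, r1 = int(np.floor(miny)), int(np.ceil(maxy))
    if c1 <= c0 or r1 <= r0:
        return np.zeros((0, 0), dtype=bool), (c0, r0)
    xs = np.arange(c0, c1) + 0.5
    ys = np.arange(r0, r1) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gy.shape)
    return inside, (c0, r0)


def rasterize_polygon(poly: Polygon, shape: tuple[int, int], origin: tuple[int, int] = (0, 0)) -> np.ndarray:
    """Boolean raster of a polygon on a full frame (see rasterize_polygon_patch)."""
    h, w = shape
    ox, oy = origin
    out = np.zeros(shape, dtype=bool)
    patch, (px0, py0) = rasterize_polygon_patch(poly)
    if patch.size == 0:
        return out
    # clip the patch to the frame
    c0, r0 = px0 - ox, py0 - oy
    c1, r1 = c0 + patch.shape[1], r0 + patch.shape[0]
    sc0, sr0 = max(c0, 0), max(r0, 0)
    sc1, sr1 = min(c1, w), min(r1, h)
    if sc1 <= sc0 or sr1 <= sr0:
        return out
    out[sr0:sr1, sc0:sc1] = patch[sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0]
    return out


def polygons_to_labels(
    a: AnnotationSet, shape: tuple[int, int], origin: tuple[int, int] = (0, 0)
) -> LabelImage:
    """Rasterize polygons into a label image (label i+1 for the i-th polygon)."""
    h, w = shape
    ox, oy = origin
    out = np.zeros(shape, dtype=np.int32)
    for i, ann in enumerate(a, start=1):
        minx, miny, maxx, maxy = ann.polygon.bounds
        if minx < ox or miny < oy or maxx > ox + w or maxy > oy + h:
            raise ExtentError(
                f"polygon {i} with bounds {ann.polygon.bounds} lies outside the "
                f"target extent [{ox},{ox + w})x[{oy},{oy + h})"
            )
        mask = rasterize_polygon(ann.polygon, shape, origin)
        out[mask] = i
    return LabelImage(out)


# ---------------------------------------------------------------------------
# GeoJSON (QuPath dialect)
# ---------------------------------------------------------------------------


def _polygon_from_coords(coords) -> Polygon:
    shell = coords[0]
    holes = coords[1:] if len(coords) > 1 else None
    poly = Polygon(shell, holes)
    if not poly.is_valid:
        poly = poly.buffer(0)
        if isinstance(poly, MultiPolygon):
            poly = max(poly.geoms, key=lambda g: g.area)
    return poly


def read_geojson(path) -> AnnotationSet:
    """Read a QuPath-dialect GeoJSON FeatureCollection.

    Polygon and MultiPolygon geometries are supported; MultiPolygons are
    split into one annotation per part. The class name is taken from the
    feature's ``classification`` property; features without one default to
    "unclassified" (with a logged warning). Features without geometry are
    skipped with a warning.
    """
    with open(path) as f:
        try:
            doc = json.load(f)
        except json.JSONDecodeError as e:
            raise ParseError(f"{path}: invalid JSON ({e})") from e
    features = doc.get("features", [])
    anns: list[Annotation] = []
    for feat in features:
        geom = feat.get("geometry")
        if geom is None:
            logger.warning("feature without geometry skipped")
            continue
        props = feat.get("properties") or {}
        classification = props.get("classification")
        if classification and "name" in classification:
            class_label = classification["name"]
        else:
            class_label = "unclassified"
            logger.warning("feature without classification; defaulting to 'unclassified'")
        gtype = geom.get("type")
        if gtype == "Polygon":
            polys = [_polygon_from_coords(geom["coordinates"])]
        elif gtype == "MultiPolygon":
            polys = [_polygon_from_coords(c) for c in geom["coordinates"]]
        else:
            logger.warning("unsupported geometry type %r skipped", gtype)
            continue
        extra = {k: v for k, v in props.items() if k != "classification"}
        for p in polys:
            if len(p.exterior.coords) < 4:
                logger.warning("degenerate polygon (<3 vertices) skipped")
                continue
            anns.append(Annotation(p, class_label, dict(extra)))
    return AnnotationSet(anns)


def write_geojson(a: AnnotationSet, path) -> None:
    """Write annotations as a QuPath-compatible GeoJSON FeatureCollection."""
    features = []
    for ann in a:
        props = dict(ann.properties)
        props["classification"] = {"name": ann.class_label}
        props.setdefault("objectType", "annotation")
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(ann.polygon),
                "properties": props,
            }
        )
    with open(path, "w") as f:
        json.dump({"type": "FeatureCollection", "features": features}, f)


# ---------------------------------------------------------------------------
# Calibrated TIFF I/O
# ---------------------------------------------------------------------------


def write_calibrated_tiff(img: CalibratedImage, path) -> None:
    """Write an RGB TIFF, recording the pixel size in the image description."""
    tifffile.imwrite(
        path,
        img.pixels,
        photometric="rgb",
        description=json.dumps({"pixel_size_um": img.pixel_size_um}),
    )


def read_calibrated_tiff(path, pixel_size_um: float | None = None) -> CalibratedImage:
    """Read an RGB TIFF; pixel size from the description unless overridden."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        if pixel_size_um is None:
            desc = tf.pages[0].description or ""
            try:
                pixel_size_um = float(json.loads(desc)["pixel_size_um"])
            except (json.JSONDecodeError, KeyError, TypeError, ValueError):
                raise FormatError(
                    f"{path}: no pixel_size_um in TIFF description; pass it explicitly"
                )
    if arr.ndim == 2:
        raise FormatError(f"{path}: expected RGB, got single channel")
    return CalibratedImage(arr[..., :3], pixel_size_um)
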