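"""Pluggable tile segmenters.

A segmentation backend is any callable ``(tile: CalibratedImage,
params: SegmentationParams) -> LabelImage`` returning an instance label
image of the tile's shape. Three backends ship here:

* :func:`oracle_backend` — crops a synthetic scene's ground truth (optionally
  perturbed per tile, deterministically); the workhorse for testing the
  reconstruction and measurement stages independently of any model.
* :func:`null_backend` — returns background everywhere.
* :func:`cellpose_backend` — a thin adapter around the optional ``cellpose``
  package, treated strictly as a black box; its weights and internals are
  the user's responsibility (``model_id`` is passed through opaquely).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .errors import CapabilityError, ContractViolationError, ExtentError, ParameterError
from .imaging import CalibratedImage, LabelImage

__all__ = [
    "SegmentationParams",
    "SegmenterContract",
    "select_channel",
    "segment_tile",
    "oracle_backend",
    "null_backend",
    "cellpose_backend",
]

_CHANNELS = ("red", "green", "blue", "gray")


@dataclass
class SegmentationParams:
    """Backend-facing segmentation parameters.

    Defaults are the tuned configuration: 50 px estimated cell diameter on
    the blue channel, flow threshold 0.5, resampling on.
    """

    diameter_px: int = 50
    channel: str = "blue"
    flow_threshold: float = 0.5
    resample: bool = True
    model_id: str = ""

    def __post_init__(self) -> None:
        if self.diameter_px <= 0:
            raise ParameterError(f"diameter_px must be > 0, got {self.diameter_px}")
        if self.channel not in _CHANNELS:
            raise ParameterError(
                f"channel must be one of {_CHANNELS}, got {self.channel!r}"
            )


SegmenterContract = Callable[[CalibratedImage, SegmentationParams], LabelImage]


def select_channel(img: CalibratedImage, channel: str) -> np.ndarray:
    """Extract one plane; 'gray' is the rounded unweighted mean of R, G, B."""
    if channel == "red":
        return img.pixels[..., 0].copy()
    if channel == "green":
        return img.pixels[..., 1].copy()
    if channel == "blue":
        return img.pixels[..., 2].copy()
    if channel == "gray":
        return np.rint(img.pixels.astype(np.float64).mean(axis=2)).astype(np.uint8)
    raise ParameterError(f"unknown channel {channel!r}; expected one of {_CHANNELS}")


def segment_tile(
    backend: SegmenterContract, tile: CalibratedImage, params: SegmentationParams
) -> LabelImage:
    """Run a backend on one tile and validate its output contract.

    Backend outputs are never trusted: shape and label validity are checked
    here so downstream modules may assume the LabelImage invariants hold.
    """
    original = tile.pixels.copy()
    out = backend(tile, params)
    if not isinstance(out, LabelImage):
        raise ContractViolationError(
            f"backend {getattr(backend, '__name__', backend)!r} returned "
            f"{type(out).__name__}, not a LabelImage"
        )
    if out.shape != tile.shape:
        raise ContractViolationError(
            f"backend {getattr(backend, '__name__', backend)!r} returned shape "
            f"{out.shape}, expected {tile.shape}"
        )
    if not np.array_equal(tile.pixels, original):
        raise ContractViolationError("backend mutated its input tile")
    return out


def null_backend(tile: CalibratedImage, params: SegmentationParams) -> LabelImage:
    """Backend producing no masks (all background)."""
    return LabelImage(np.zeros(tile.shape, dtype=np.int32))


def oracle_backend(scene, perturbation=None) -> SegmenterContract:
    """Segmenter that returns the planted ground truth of a synthetic scene.

    The returned callable crops the scene's ground-truth label image to the
    requested tile, located by pixel-matching the tile content against the
    scene image. If a perturbation spec is given, it is applied per tile
    with a seed derived from the tile origin, so repeated calls on the same
    tile are identical.

    Parameters
    ----------
    scene : synthetic.SyntheticScene
        Scene carrying ground-truth labels.
    perturbation : synthetic.PerturbationSpec, optional
        Label-noise spec applied deterministically per tile.
    """
    from .synthetic import perturb_labels  # local import to avoid a cycle

    scene_pixels = scene.image.pixels
    gt = scene.gt_fibers.labels
    sh, sw = gt.shape

    def _locate(tile: CalibratedImage) -> tuple[int, int]:
        # tiles from extract_tile carry their origin; otherwise find it by
        # exact template match (scene textures make the match unique in practice)
        th, tw = tile.shape
        if th > sh or tw > sw:
            raise ExtentError("tile larger than scene")
        k = min(8, th, tw)
        patch = tile.pixels[:k, :k]
        for y0 in range(sh - th + 1):
            for x0 in range(sw - tw + 1):
                if np.array_equal(scene_pixels[y0 : y0 + k, x0 : x0 + k], patch) and np.array_equal(
                    scene_pixels[y0 : y0 + th, x0 : x0 + tw], tile.pixels
                ):
                    return x0, y0
        raise ExtentError("tile not found within scene")

    def segmenter(tile: CalibratedImage, params: SegmentationParams) -> LabelImage:
        origin = getattr(tile, "origin", None)
        if origin is None:
            x0, y0 = _locate(tile)
        else:
            x0, y0 = origin
        th, tw = tile.shape
        if x0 < 0 or y0 < 0 or x0 + tw > sw or y0 + th > sh:
            raise ExtentError(
                f"tile [{x0},{x0 + tw})x[{y0},{y0 + th}) outside scene {sw}x{sh}"
            )
        crop = LabelImage(gt[y0 : y0 + th, x0 : x0 + tw].copy())
        if perturbation is not None:
            # derive a per-tile seed from the tile origin so outputs repeat
            tile_seed = (perturbation.seed * 1_000_003 + x0 * 7919 + y0 * 104729) % (2**31)
            spec = perturbation.with_seed(tile_seed)
            crop, _ = perturb_labels(crop, spec)
        return crop

    segmenter.__name__ = "oracle_backend"
    return segmenter


def cellpose_backend(device: Optional[str] = None) -> SegmenterContract:
    """Adapter around the optional cellpose package (used as a black box).

    Raises a capability error if cellpose is not installed. ``model_id``
    in the params selects a pretrained or user fine-tuned model.
    """
    try:
        from cellpose import models  # type: ignore
    except ImportError as e:
        raise CapabilityError(
            "cellpose is not installed; install the 'cellpose' extra "
            "(pip install myofiberquant[cellpose]) or use --backend oracle/none"
        ) from e

    def segmenter(tile: CalibratedImage, params: SegmentationParams) -> LabelImage:
        plane = select_channel(tile, params.channel)
        model = models.CellposeModel(
            pretrained_model=params.model_id or None, device=device
        )
        masks = model.eval(
            plane,
            diameter=params.diameter_px,
            flow_threshold=params.flow_threshold,
            resample=params.resample,
            channels=[0, 0],
        )[0]
        return LabelImage(np.asarray(masks, dtype=np.int32))

    segmenter.__name__ = "cellpose_backend"
    return segmenter
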