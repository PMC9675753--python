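"""Synthetic H&E-like muscle cross-sections with known ground truth.

Scenes emulate the statistics that matter to the pipeline rather than
photorealism: tightly packed convex-leaning fiber polygons (a jittered
lattice tessellation, per-fiber rescaled to draw minimal Feret diameters
from a lognormal), dark nuclei planted peripherally or centrally with a
controlled probability and a construction margin of at least 1 um around
the 2.2 um centrality threshold, dark-blob and tear artifacts, and
cohort-level parameter shifts emulating wild-type / knockout / dose-response
groups. Everything is deterministic per seed, so every pipeline stage can
be tested against planted truth.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import Voronoi
from shapely import affinity
from shapely.geometry import Point, Polygon, box

from .errors import ParameterError
from .imaging import (
    Annotation,
    AnnotationSet,
    CalibratedImage,
    LabelImage,
    rasterize_polygon_patch,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Palette",
    "ArtifactSpec",
    "SectionSpec",
    "SyntheticScene",
    "PerturbationSpec",
    "CohortSpec",
    "generate_section",
    "perturb_labels",
    "generate_cohort",
    "default_cohort_spec",
]


@dataclass
class Palette:
    """Mean RGB colors of scene materials, with per-fiber jitter and noise."""

    cytoplasm: tuple[int, int, int] = (226, 148, 158)
    boundary: tuple[int, int, int] = (243, 224, 229)
    nucleus: tuple[int, int, int] = (88, 58, 122)
    background: tuple[int, int, int] = (246, 244, 246)
    artifact_dark: tuple[int, int, int] = (60, 45, 50)
    fiber_jitter: int = 8
    noise_sd: float = 4.0


@dataclass
class ArtifactSpec:
    """Dark-blob (dust/fold) and tear (white streak) artifact counts and sizes."""

    n_dark_blobs: int = 3
    n_tears: int = 1
    blob_radius_um: tuple[float, float] = (8.0, 30.0)
    tear_width_um: tuple[float, float] = (3.0, 8.0)
    tear_length_um: tuple[float, float] = (80.0, 250.0)


@dataclass
class SectionSpec:
    """Parameters of one synthetic section.

    ``fiber_median_um`` and ``fiber_sigma`` parametrize the lognormal of
    minimal Feret diameters (median in um, log-space sigma). Nuclei are
    planted per fiber (count uniform in ``nuclei_per_fiber``), each flagged
    central with probability ``p_central_nucleus``; central nuclei keep
    their boundary > 3.2 um from the sarcolemma and peripheral ones < 1.2
    um, i.e. at least 1 um of margin on either side of the 2.2 um rule.
    ``max_extent_px`` optionally caps each fiber's maximal Feret extent.
    """

    seed: int = 0
    width_px: int = 1024
    height_px: int = 1024
    pixel_size_um: float = 0.5
    fiber_median_um: float = 40.0
    fiber_sigma: float = 0.3
    boundary_thickness_um: float = 1.5
    p_central_nucleus: float = 0.05
    nuclei_per_fiber: tuple[int, int] = (1, 2)
    nucleus_radius_um: tuple[float, float] = (1.5, 2.5)
    spacing_factor: float | None = None  # default exp(1.5 * fiber_sigma)
    lattice_jitter: float = 0.35
    elongation: float = 0.0
    max_extent_px: float | None = None
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    palette: Palette = field(default_factory=Palette)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_central_nucleus <= 1.0:
            raise ParameterError("p_central_nucleus must be in [0, 1]")
        for name in ("pixel_size_um", "fiber_median_um", "boundary_thickness_um"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")


@dataclass
class SyntheticScene:
    """A generated section with full ground truth."""

    image: CalibratedImage
    gt_fibers: LabelImage
    gt_nuclei: AnnotationSet  # properties: central (bool), fiber_label (int)
    gt_artifacts: np.ndarray  # bool mask
    spec: SectionSpec
    fiber_polygons: dict[int, Polygon] = field(default_factory=dict)
    planted_cnf: dict[int, bool] = field(default_factory=dict)
    planted_min_feret_um: dict[int, float] = field(default_factory=dict)


@dataclass
class PerturbationSpec:
    """Controlled label noise for manufacturing imperfect predictions."""

    seed: int = 0
    drop_rate: float = 0.0
    boundary_jitter_px: int = 0
    spurious_rate: float = 0.0  # expected spurious blobs per 1000x1000 px
    split_rate: float = 0.0
    merge_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("drop_rate", "split_rate", "merge_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.boundary_jitter_px < 0 or self.spurious_rate < 0:
            raise ParameterError("boundary_jitter_px and spurious_rate must be >= 0")

    def with_seed(self, seed: int) -> "PerturbationSpec":
        return dataclasses.replace(self, seed=seed)


@dataclass
class CohortSpec:
    """Named groups of sections with per-group SectionSpec overrides."""

    groups: list[tuple[str, int, dict]]
    base: SectionSpec = field(default_factory=SectionSpec)
    master_seed: int = 0


# ---------------------------------------------------------------------------
# Section generation
# ---------------------------------------------------------------------------


def _lattice_sites(w: int, h: int, spacing: float, jitter: float, rng) -> np.ndarray:
    """Jittered square lattice covering the image plus a margin ring."""
    margin = 2
    xs = np.arange(-margin, int(np.ceil(w / spacing)) + margin + 1) * spacing
    ys = np.arange(-margin, int(np.ceil(h / spacing)) + margin + 1) * spacing
    gx, gy = np.meshgrid(xs, ys)
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    pts += rng.uniform(-jitter * spacing, jitter * spacing, size=pts.shape)
    return pts


def _voronoi_cells(sites: np.ndarray, w: int, h: int) -> list[Polygon]:
    """Bounded Voronoi cells clipped to the image box (in site order subset)."""
    vor = Voronoi(sites)
    frame = box(0, 0, w, h)
    cells = []
    for i in range(len(sites)):
        region = vor.regions[vor.point_region[i]]
        if not region or -1 in region:
            continue
        poly = Polygon(vor.vertices[region])
        if not poly.is_valid:
            continue
        clipped = poly.intersection(frame)
        if clipped.is_empty or clipped.geom_type != "Polygon" or clipped.area < 9:
            continue
        cells.append(clipped)
    return cells


def _max_feret_px(poly: Polygon) -> float:
    pts = np.asarray(poly.convex_hull.exterior.coords)[:-1]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _sample_point_in(poly: Polygon, rng, tries: int = 64) -> Point | None:
    minx, miny, maxx, maxy = poly.bounds
    for _ in range(tries):
        p = Point(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if poly.contains(p):
            return p
    rp = poly.representative_point()
    return rp if poly.contains(rp) else None


def _circle(center: Point, radius_px: float, n: int = 24) -> Polygon:
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Polygon(
        np.stack(
            [center.x + radius_px * np.cos(ang), center.y + radius_px * np.sin(ang)],
            axis=1,
        )
    )


def generate_section(spec: SectionSpec) -> SyntheticScene:
    """Generate one synthetic section; fully deterministic per seed."""
    from .morphometry import min_feret_diameter

    rng = np.random.default_rng(spec.seed)
    w, h = spec.width_px, spec.height_px
    px = spec.pixel_size_um
    spacing_factor = (
        spec.spacing_factor
        if spec.spacing_factor is not None
        else float(np.exp(1.5 * spec.fiber_sigma))
    )
    spacing_px = spec.fiber_median_um * spacing_factor / px
    sites = _lattice_sites(w, h, spacing_px, spec.lattice_jitter, rng)
    cells = _voronoi_cells(sites, w, h)
    # stable order: top-left to bottom-right by centroid
    cells.sort(key=lambda c: (round(c.centroid.y, 3), round(c.centroid.x, 3)))

    gap_px = spec.boundary_thickness_um / px / 2.0
    inners: list[tuple[Polygon, float]] = []
    for cell in cells:
        inner = cell.buffer(-gap_px, join_style=2)
        if inner.is_empty or inner.geom_type != "Polygon" or inner.area < 9:
            continue
        try:
            cell_mf_um = min_feret_diameter(inner, px)
        except Exception:
            continue
        inners.append((inner, cell_mf_um))

    # draw all target diameters, then assign the k-th largest draw to the
    # k-th roomiest cell: the capacity cap (a fiber cannot outgrow its
    # lattice cell) then almost never binds, so the planted minimal-Feret
    # sample tracks the lognormal
    targets_um = spec.fiber_median_um * np.exp(
        spec.fiber_sigma * rng.normal(size=len(inners))
    )
    rank_of_cell = np.argsort(np.argsort([mf for _, mf in inners]))
    sorted_targets = np.sort(targets_um)
    fibers: list[Polygon] = []
    for (inner, cell_mf_um), rank in zip(inners, rank_of_cell):
        target_um = float(sorted_targets[rank])
        f = min(1.0, target_um / cell_mf_um)
        if spec.elongation > 0:
            fx, fy = f * (1 + spec.elongation), f / (1 + spec.elongation)
        else:
            fx = fy = f
        poly = affinity.scale(inner, xfact=fx, yfact=fy, origin="centroid")
        if spec.max_extent_px is not None:
            ext = _max_feret_px(poly)
            if ext > spec.max_extent_px:
                shrink = spec.max_extent_px / ext * 0.999
                poly = affinity.scale(poly, xfact=shrink, yfact=shrink, origin="centroid")
        poly = poly.intersection(box(0, 0, w, h))
        if poly.is_empty or poly.geom_type != "Polygon" or poly.area < 9:
            continue
        fibers.append(poly)

    # artifacts as shapes first, so affected fibers can be excluded from truth
    art = spec.artifact_spec
    artifact_shapes: list[tuple[Polygon, str]] = []
    for _ in range(art.n_dark_blobs):
        r = rng.uniform(*art.blob_radius_um) / px
        c = Point(rng.uniform(0, w), rng.uniform(0, h))
        blob = affinity.rotate(
            affinity.scale(_circle(c, r), 1.0, rng.uniform(0.6, 1.0)),
            rng.uniform(0, 180),
        ).intersection(box(0, 0, w, h))
        if not blob.is_empty:
            artifact_shapes.append((blob, "dark"))
    for _ in range(art.n_tears):
        width = rng.uniform(*art.tear_width_um) / px
        length = rng.uniform(*art.tear_length_um) / px
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        strip = box(cx - length / 2, cy - width / 2, cx + length / 2, cy + width / 2)
        strip = affinity.rotate(strip, rng.uniform(0, 180)).intersection(box(0, 0, w, h))
        if not strip.is_empty:
            artifact_shapes.append((strip, "tear"))

    kept: list[Polygon] = []
    for poly in fibers:
        if any(poly.intersects(s) for s, _ in artifact_shapes):
            continue  # artifact-covered fibers are excluded from ground truth
        kept.append(poly)

    # rasterize fibers and plant nuclei
    labels = np.zeros((h, w), dtype=np.int32)
    fiber_polygons: dict[int, Polygon] = {}
    planted_mf: dict[int, float] = {}
    patches: dict[int, tuple[np.ndarray, tuple[int, int]]] = {}
    lab = 0
    for poly in kept:
        patch, (x0, y0) = rasterize_polygon_patch(poly)
        if patch.size == 0 or not patch.any():
            continue
        lab += 1
        region = labels[y0 : y0 + patch.shape[0], x0 : x0 + patch.shape[1]]
        region[patch] = lab
        fiber_polygons[lab] = poly
        planted_mf[lab] = min_feret_diameter(poly, px)
        patches[lab] = (patch, (x0, y0))

    central_margin_um = 1.2  # > 1 um beyond the 2.2 um rule
    nuclei: list[Annotation] = []
    planted_cnf: dict[int, bool] = {}
    for flab, poly in fiber_polygons.items():
        planted_cnf[flab] = False
        n_nuc = int(rng.integers(spec.nuclei_per_fiber[0], spec.nuclei_per_fiber[1] + 1))
        for _ in range(n_nuc):
            central = bool(rng.random() < spec.p_central_nucleus)
            r_um = rng.uniform(*spec.nucleus_radius_um)
            r_px = r_um / px
            if central:
                gap_um = rng.uniform(2.2 + central_margin_um, 2.2 + central_margin_um + 3.0)
            else:
                gap_um = rng.uniform(0.15, 2.2 - central_margin_um)
            depth_px = (r_um + gap_um) / px
            inner = poly.buffer(-depth_px)
            if inner.is_empty:
                if central:
                    # fiber too small for a central nucleus: replant peripherally
                    central = False
                    gap_um = rng.uniform(0.15, 2.2 - central_margin_um)
                    depth_px = (r_um + gap_um) / px
                    inner = poly.buffer(-depth_px)
                if inner.is_empty:
                    logger.info("fiber %d too small for a nucleus; skipped", flab)
                    continue
            if inner.geom_type != "Polygon":
                inner = max(inner.geoms, key=lambda g: g.area)
            if central:
                center = _sample_point_in(inner, rng)
                if center is None:
                    continue
            else:
                # place on the iso-depth contour so the planted gap is exact
                ring = inner.exterior
                center = ring.interpolate(rng.uniform(0, ring.length))
            nucleus = _circle(Point(center), r_px)
            nuclei.append(
                Annotation(nucleus, "nucleus", {"central": central, "fiber_label": flab})
            )
            if central:
                planted_cnf[flab] = True

    # render
    pal = spec.palette
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = pal.background
    fiber_mask = labels > 0
    halo_px = max(1, int(round(spec.boundary_thickness_um / px)) + 1)
    halo = ndimage.binary_dilation(fiber_mask, iterations=halo_px) & ~fiber_mask
    img[halo] = pal.boundary
    for flab, (patch, (x0, y0)) in patches.items():
        jit = rng.uniform(-pal.fiber_jitter, pal.fiber_jitter, size=3)
        color = np.clip(np.array(pal.cytoplasm, dtype=np.float64) + jit, 0, 255)
        region = img[y0 : y0 + patch.shape[0], x0 : x0 + patch.shape[1]]
        region[patch] = color
    for ann in nuclei:
        patch, (x0, y0) = rasterize_polygon_patch(ann.polygon)
        if patch.size:
            region = img[y0 : y0 + patch.shape[0], x0 : x0 + patch.shape[1]]
            region[patch] = pal.nucleus
    artifact_mask = np.zeros((h, w), dtype=bool)
    for s, kind in artifact_shapes:
        if s.geom_type != "Polygon":
            s = max(s.geoms, key=lambda g: g.area)
        patch, (x0, y0) = rasterize_polygon_patch(s)
        if not patch.size:
            continue
        # clip patch to frame
        sx0, sy0 = max(x0, 0), max(y0, 0)
        sx1 = min(x0 + patch.shape[1], w)
        sy1 = min(y0 + patch.shape[0], h)
        if sx1 <= sx0 or sy1 <= sy0:
            continue
        sub = patch[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0]
        artifact_mask[sy0:sy1, sx0:sx1] |= sub
        color = pal.artifact_dark if kind == "dark" else (252, 252, 252)
        img[sy0:sy1, sx0:sx1][sub] = color
    if pal.noise_sd > 0:
        img += rng.normal(0, pal.noise_sd, size=img.shape)
    image = CalibratedImage(np.clip(img, 0, 255).astype(np.uint8), px)

    return SyntheticScene(
        image=image,
        gt_fibers=LabelImage(labels),
        gt_nuclei=AnnotationSet(nuclei),
        gt_artifacts=artifact_mask,
        spec=spec,
        fiber_polygons=fiber_polygons,
        planted_cnf=planted_cnf,
        planted_min_feret_um=planted_mf,
    )


# ---------------------------------------------------------------------------
# Label perturbation
# ---------------------------------------------------------------------------


def perturb_labels(gt: LabelImage, p: PerturbationSpec) -> tuple[LabelImage, dict]:
    """Apply controlled noise to an instance label image.

    Returns the perturbed labels and a log recording exactly which labels
    were dropped, jittered, split, merged, and which spurious labels were
    added, so tests can derive expected TP/FP/FN analytically.
    """
    rng = np.random.default_rng(p.seed)
    labels = gt.labels.copy()
    h, w = labels.shape
    log = {"dropped": [], "jitter": {}, "spurious": [], "split": {}, "merged": {}}
    present = [int(v) for v in np.unique(labels) if v > 0]
    next_label = (max(present) + 1) if present else 1

    # drops (i.i.d. per mask)
    for lab in present:
        if rng.random() < p.drop_rate:
            labels[labels == lab] = 0
            log["dropped"].append(lab)
    survivors = [lab for lab in present if lab not in log["dropped"]]

    # boundary jitter: per-mask erode (k<0) / dilate (k>0), radius |k|
    if p.boundary_jitter_px > 0:
        j = p.boundary_jitter_px
        for lab in survivors:
            k = int(rng.integers(-j, j + 1))
            log["jitter"][lab] = k
            if k == 0:
                continue
            mask = labels == lab
            sl = ndimage.find_objects(mask.astype(np.int8))[0]
            pad = abs(k) + 1
            r0, r1 = max(sl[0].start - pad, 0), min(sl[0].stop + pad, h)
            c0, c1 = max(sl[1].start - pad, 0), min(sl[1].stop + pad, w)
            sub = mask[r0:r1, c0:c1]
            if k > 0:
                grown = ndimage.binary_dilation(sub, iterations=k)
                # expand only into background
                target = labels[r0:r1, c0:c1]
                newpix = grown & (target == 0)
                target[newpix] = lab
            else:
                shrunk = ndimage.binary_erosion(sub, iterations=-k)
                if not shrunk.any():
                    log["jitter"][lab] = 0  # would erase the mask; skipped
                    continue
                target = labels[r0:r1, c0:c1]
                target[sub & ~shrunk] = 0

    # splits: cut through the centroid column, right part gets a fresh label
    for lab in list(survivors):
        if p.split_rate and rng.random() < p.split_rate:
            rows, cols = np.nonzero(labels == lab)
            if cols.size < 8:
                continue
            cut = int(np.median(cols))
            right = (labels == lab) & (np.arange(w)[None, :] > cut)
            if right.any() and right.sum() < cols.size:
                labels[right] = next_label
                log["split"][lab] = next_label
                next_label += 1

    # merges: absorb the nearest neighbor (by bbox distance) into this mask
    if p.merge_rate:
        slices = {lab: sl for lab, sl in zip(range(1, labels.max() + 1), ndimage.find_objects(labels)) if sl is not None}
        merged_away = set()
        keepers = set()
        for lab in list(slices):
            if lab in merged_away or rng.random() >= p.merge_rate:
                continue
            sl = slices[lab]
            best, best_d = None, 40.0
            for other, osl in slices.items():
                # never absorb a mask that already merged (either role), so the
                # log stays flat: absorbed pixels always carry their keeper
                if other == lab or other in merged_away or other in keepers:
                    continue
                dy = max(osl[0].start - sl[0].stop, sl[0].start - osl[0].stop, 0)
                dx = max(osl[1].start - sl[1].stop, sl[1].start - osl[1].stop, 0)
                d = float(np.hypot(dx, dy))
                if d < best_d:
                    best, best_d = other, d
            if best is not None:
                labels[labels == best] = lab
                merged_away.add(best)
                keepers.add(lab)
                log["merged"][lab] = log["merged"].get(lab, []) + [best]

    # spurious small blobs on background
    if p.spurious_rate > 0:
        n_spur = int(rng.poisson(p.spurious_rate * h * w / 1_000_000))
        for _ in range(n_spur):
            for _try in range(30):
                r = int(rng.integers(3, 9))
                cy = int(rng.integers(r, h - r))
                cx = int(rng.integers(r, w - r))
                yy, xx = np.ogrid[-r : r + 1, -r : r + 1]
                disk = yy**2 + xx**2 <= r**2
                region = labels[cy - r : cy + r + 1, cx - r : cx + r + 1]
                if (region[disk] == 0).all():
                    region[disk] = next_label
                    log["spurious"].append(next_label)
                    next_label += 1
                    break
    return LabelImage(labels), log


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def default_cohort_spec(
    master_seed: int = 0,
    n_sections: int = 2,
    width_px: int = 1280,
    height_px: int = 1280,
) -> CohortSpec:
    """The study-design analog: WT, KO and three treatment doses.

    Group parameters encode the dystrophic phenotype and its dose-dependent
    rescue: knockouts have smaller, more heterogeneous fibers and a high
    central-nucleation probability; increasing vector dose moves all three
    indicators back toward wild type.
    """
    base = SectionSpec(width_px=width_px, height_px=height_px)
    groups = [
        ("WT", n_sections, dict(fiber_median_um=40.0, fiber_sigma=0.25, p_central_nucleus=0.01)),
        ("dose_high", n_sections, dict(fiber_median_um=38.0, fiber_sigma=0.30, p_central_nucleus=0.06)),
        ("dose_mid", n_sections, dict(fiber_median_um=33.0, fiber_sigma=0.38, p_central_nucleus=0.12)),
        ("dose_low", n_sections, dict(fiber_median_um=30.0, fiber_sigma=0.44, p_central_nucleus=0.20)),
        ("KO", n_sections, dict(fiber_median_um=28.0, fiber_sigma=0.50, p_central_nucleus=0.30)),
    ]
    return CohortSpec(groups=groups, base=base, master_seed=master_seed)


def generate_cohort(c: CohortSpec) -> list[tuple[str, SyntheticScene]]:
    """Generate every group's sections with independent derived seeds."""
    out: list[tuple[str, SyntheticScene]] = []
    for gi, (name, n_sections, overrides) in enumerate(c.groups):
        for si in range(n_sections):
            seed = int(
                np.random.SeedSequence([c.master_seed, gi, si]).generate_state(1)[0]
                % (2**31)
            )
            spec = dataclasses.replace(c.base, seed=seed, **overrides)
            out.append((name, generate_section(spec)))
    return out
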