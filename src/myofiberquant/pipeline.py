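"""End-to-end orchestration: tile, segment, reconstruct, filter, measure, report.

Stage order follows the workflow overview: tissue detection, tiling, per-tile
segmentation, whole-slide mask reconstruction, artifact filtering, then
morphometry. Runs are recorded in a JSON manifest (parameters, outputs,
content hashes) and are idempotent: a re-run with an unchanged configuration
skips completed sections unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import backends as _backends
from .artifacts import MaskFilterParams, PixelClassifierModel, filter_masks
from .errors import ConfigError, StageError
from .evaluation import MatchParams
from .imaging import (
    AnnotationSet,
    CalibratedImage,
    LabelImage,
    TileName,
    labels_to_polygons,
    read_calibrated_tiff,
    read_geojson,
    write_geojson,
    write_label_image,
)
from .morphometry import (
    CnfParams,
    SectionSummary,
    detect_nuclei,
    measure_section,
    summarize_section,
)
from .reconstruction import reconstruct_wsi
from .tiling import BoundingBox, TileParams, TissueParams, detect_tissue, extract_tile, make_tiles

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "CohortReport",
    "run_scene_pipeline",
    "run_pipeline",
    "build_cohort_report",
    "measurements_to_frame",
    "summary_to_row",
]


@dataclass
class PipelineConfig:
    """All per-stage parameter blocks; defaults are the tuned configuration."""

    tissue: TissueParams = field(default_factory=TissueParams)
    tiles: TileParams = field(default_factory=TileParams)
    segmentation: _backends.SegmentationParams = field(
        default_factory=_backends.SegmentationParams
    )
    backend: str = "none"  # none | cellpose (oracle needs a scene, see run_scene_pipeline)
    filter_params: MaskFilterParams = field(default_factory=MaskFilterParams)
    filter_model_path: str | None = None
    cnf: CnfParams = field(default_factory=CnfParams)
    match: MatchParams = field(default_factory=MatchParams)
    nuclei_mode: str = "detect"  # detect | oracle | geojson:<path>
    master_seed: int = 0

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            return obj

        return {
            "tissue": enc(self.tissue),
            "tiles": enc(self.tiles),
            "segmentation": enc(self.segmentation),
            "backend": self.backend,
            "filter_params": enc(self.filter_params),
            "filter_model_path": self.filter_model_path,
            "cnf": enc(self.cnf),
            "match": enc(self.match),
            "nuclei_mode": self.nuclei_mode,
            "master_seed": self.master_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = {}
        blocks = {
            "tissue": TissueParams,
            "tiles": TileParams,
            "segmentation": _backends.SegmentationParams,
            "filter_params": MaskFilterParams,
            "cnf": CnfParams,
            "match": MatchParams,
        }
        for key, typ in blocks.items():
            if key in d:
                kwargs[key] = typ(**d[key]) if isinstance(d[key], dict) else d[key]
        for key in ("backend", "filter_model_path", "nuclei_mode", "master_seed"):
            if key in d:
                kwargs[key] = d[key]
        try:
            return cls(**kwargs)
        except TypeError as e:
            raise ConfigError(str(e)) from e


@dataclass
class CohortReport:
    per_section: pd.DataFrame  # one row per section, with a 'group' column
    per_group: pd.DataFrame  # mean +- sd aggregates per group
    pooled_histograms: dict[str, np.ndarray]
    bin_width_um: float = 5.0


def _resolve_backend(cfg: PipelineConfig):
    if cfg.backend == "none":
        return _backends.null_backend
    if cfg.backend == "cellpose":
        return _backends.cellpose_backend()
    raise ConfigError(f"unknown backend {cfg.backend!r}; expected 'none' or 'cellpose'")


def run_scene_pipeline(
    scene,
    cfg: PipelineConfig | None = None,
    perturbation=None,
    backend=None,
    filter_model: PixelClassifierModel | None = None,
    slide_id: str = "scene",
) -> dict:
    """Run the tile/segment/reconstruct/measure pipeline on a synthetic scene.

    The backend defaults to the scene's oracle (ground-truth crops, with
    optional perturbation). Returns a dict with the reconstructed labels,
    the placed masks, the per-fiber measurements and the section summary.
    """
    cfg = cfg or PipelineConfig()
    h, w = scene.image.shape
    grid = make_tiles(BoundingBox(0, 0, w, h), cfg.tiles)
    if backend is None:
        backend = _backends.oracle_backend(scene, perturbation)
    tile_labels = []
    for t in grid:
        tile = extract_tile(scene.image, t)
        out = _backends.segment_tile(backend, tile, cfg.segmentation)
        tile_labels.append((out, TileName(slide_id, t.x0, t.y0)))
    labels, placed = reconstruct_wsi(tile_labels, grid, (h, w))
    removal_report = []
    if filter_model is not None:
        labels, removal_report = filter_masks(
            labels, scene.image, filter_model, cfg.filter_params
        )
    if cfg.nuclei_mode == "oracle":
        nuclei = scene.gt_nuclei
    elif cfg.nuclei_mode == "detect":
        nuclei = detect_nuclei(scene.image)
    elif cfg.nuclei_mode.startswith("geojson:"):
        nuclei = read_geojson(cfg.nuclei_mode.split(":", 1)[1])
    else:
        raise ConfigError(f"unknown nuclei_mode {cfg.nuclei_mode!r}")
    measurements = measure_section(
        labels, scene.image.pixel_size_um, nuclei, cfg.cnf
    )
    summary = summarize_section(measurements) if measurements else None
    if not measurements:
        logger.warning("pipeline produced zero fibers; empty measurement table")
    return {
        "labels": labels,
        "placed": placed,
        "removal_report": removal_report,
        "measurements": measurements,
        "summary": summary,
        "grid": grid,
    }


_FIBER_COLUMNS = [
    "fiber_label",
    "centroid_x",
    "centroid_y",
    "area_um2",
    "min_feret_um",
    "n_nuclei",
    "n_central_nuclei",
    "is_cnf",
]


def measurements_to_frame(measurements) -> pd.DataFrame:
    """Per-fiber CSV table (one row per fiber; header is stable when empty)."""
    if not measurements:
        return pd.DataFrame(columns=_FIBER_COLUMNS)
    return pd.DataFrame(
        [
            {
                "fiber_label": m.fiber_label,
                "centroid_x": m.centroid[0],
                "centroid_y": m.centroid[1],
                "area_um2": m.area_um2,
                "min_feret_um": m.min_feret_um,
                "n_nuclei": m.n_nuclei,
                "n_central_nuclei": m.n_central_nuclei,
                "is_cnf": m.is_cnf,
            }
            for m in measurements
        ]
    )


def summary_to_row(summary: SectionSummary) -> dict:
    row = {
        "n_fibers": summary.n_fibers,
        "cnf_ratio": summary.cnf_ratio,
        "mean_min_feret_um": summary.mean_min_feret_um,
        "vc": summary.vc,
        "n_nonempty_classes": summary.n_nonempty_classes,
        "n_overflow": summary.n_overflow,
    }
    for k, c in enumerate(summary.histogram):
        row[f"hist_{int(k * summary.bin_width_um)}_{int((k + 1) * summary.bin_width_um)}"] = int(c)
    return row


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig, wsi_paths, out_dir, force: bool = False) -> dict:
    """File-based pipeline over whole-slide TIFFs; writes outputs + manifest.

    Per section: label PNG, prediction GeoJSON, per-fiber CSV and summary
    CSV. Completed sections (recorded in the manifest with a matching
    configuration) are skipped unless ``force``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    cfg_dict = cfg.to_dict()
    cfg_hash = hashlib.sha256(json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()
    manifest = {"config": cfg_dict, "config_hash": cfg_hash, "sections": {}}
    if manifest_path.exists():
        try:
            old = json.loads(manifest_path.read_text())
            if old.get("config_hash") == cfg_hash:
                manifest = old
        except json.JSONDecodeError:
            pass

    backend = _resolve_backend(cfg)
    filter_model = None
    if cfg.filter_model_path:
        from .artifacts import load_model

        filter_model = load_model(cfg.filter_model_path)

    for path in map(Path, wsi_paths):
        sid = path.stem
        entry = manifest["sections"].get(sid)
        if entry and not force and all(Path(f).exists() for f in entry["outputs"].values()):
            logger.info("section %s already complete; skipping", sid)
            continue
        try:
            img = read_calibrated_tiff(path)
            _, boxes = detect_tissue(img, cfg.tissue)
            if boxes:
                x0 = min(b.x0 for b in boxes)
                y0 = min(b.y0 for b in boxes)
                x1 = max(b.x0 + b.width for b in boxes)
                y1 = max(b.y0 + b.height for b in boxes)
                region = BoundingBox(x0, y0, x1 - x0, y1 - y0)
            else:
                region = BoundingBox(0, 0, img.shape[1], img.shape[0])
            grid = make_tiles(region, cfg.tiles)
            tile_labels = []
            for t in grid:
                tile = extract_tile(img, t)
                out = _backends.segment_tile(backend, tile, cfg.segmentation)
                tile_labels.append((out, TileName(sid, t.x0, t.y0)))
            labels, placed = reconstruct_wsi(tile_labels, grid, img.shape)
            if filter_model is not None:
                labels, _ = filter_masks(labels, img, filter_model, cfg.filter_params)
            if cfg.nuclei_mode == "detect":
                nuclei = detect_nuclei(img)
            elif cfg.nuclei_mode.startswith("geojson:"):
                nuclei = read_geojson(cfg.nuclei_mode.split(":", 1)[1])
            else:
                nuclei = AnnotationSet()
            measurements = measure_section(labels, img.pixel_size_um, nuclei, cfg.cnf)

            outputs = {
                "labels": str(out_dir / f"{sid}_labels.png"),
                "predictions": str(out_dir / f"{sid}_predictions.geojson"),
                "fibers": str(out_dir / f"{sid}_fibers.csv"),
                "summary": str(out_dir / f"{sid}_summary.csv"),
            }
            write_label_image(labels, outputs["labels"])
            write_geojson(labels_to_polygons(labels, "prediction"), outputs["predictions"])
            measurements_to_frame(measurements).to_csv(outputs["fibers"], index=False)
            if measurements:
                pd.DataFrame([summary_to_row(summarize_section(measurements))]).to_csv(
                    outputs["summary"], index=False
                )
            else:
                pd.DataFrame().to_csv(outputs["summary"], index=False)
                logger.warning("section %s: zero fibers", sid)
            manifest["sections"][sid] = {
                "outputs": outputs,
                "hashes": {k: _sha256(Path(v)) for k, v in outputs.items()},
                "n_fibers": len(measurements),
                "n_tiles": len(grid),
            }
            manifest_path.write_text(json.dumps(manifest, indent=2))
        except Exception as e:  # noqa: BLE001 - report stage + cause, keep partial manifest
            manifest_path.write_text(json.dumps(manifest, indent=2))
            raise StageError(f"section {sid}", str(e)) from e
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def build_cohort_report(
    summaries: list[tuple[str, SectionSummary]],
    out_dir=None,
    with_plots: bool = False,
    with_stats: bool = False,
) -> CohortReport:
    """Aggregate per-section summaries by group.

    Emits per-section rows, per-group mean +- sd of CNF ratio, mean minimal
    Feret diameter and variance coefficient, and pooled 5 um histograms.
    With ``with_stats``, adds stock one-way ANOVA p-values across groups
    (delegated to scipy; clearly labeled stock statistics). With
    ``with_plots`` and ``out_dir``, writes box-plot and histogram figures.
    """
    if not summaries:
        raise ConfigError("cohort report requires at least one section")
    rows = []
    for group, s in summaries:
        row = {"group": group}
        row.update(summary_to_row(s))
        rows.append(row)
    per_section = pd.DataFrame(rows)
    metrics = ["cnf_ratio", "mean_min_feret_um", "vc"]
    per_group = per_section.groupby("group", sort=False)[metrics].agg(["mean", "std", "count"])
    pooled = {}
    for group, s in summaries:
        pooled.setdefault(group, np.zeros_like(s.histogram))
        pooled[group] = pooled[group] + s.histogram
    report = CohortReport(per_section, per_group, pooled, summaries[0][1].bin_width_um)

    if with_stats and per_section["group"].nunique() > 1:
        from scipy import stats as sps

        anova = {}
        for m in metrics:
            groups = [g[m].to_numpy() for _, g in per_section.groupby("group")]
            if all(len(g) > 1 for g in groups):
                anova[m] = float(sps.f_oneway(*groups).pvalue)
        report.per_group.attrs["anova_pvalues_stock"] = anova

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        per_section.to_csv(out_dir / "cohort_sections.csv", index=False)
        per_group.to_csv(out_dir / "cohort_groups.csv")
        if with_plots:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, axes = plt.subplots(1, 3, figsize=(12, 4))
            order = list(dict.fromkeys(per_section["group"]))
            for ax, m in zip(axes, metrics):
                data = [per_section.loc[per_section.group == g, m] for g in order]
                ax.boxplot(data, tick_labels=order)
                ax.set_title(m)
                ax.tick_params(axis="x", rotation=45)
            fig.tight_layout()
            fig.savefig(out_dir / "cohort_boxplots.png", dpi=120)
            plt.close(fig)

            fig, ax = plt.subplots(figsize=(7, 4))
            bw = report.bin_width_um
            for g in order:
                hist = report.pooled_histograms[g].astype(float)
                if hist.sum():
                    hist = hist / hist.sum()
                ax.plot(np.arange(len(hist)) * bw + bw / 2, hist, label=g)
            ax.set_xlabel("minimal Feret diameter (um)")
            ax.set_ylabel("fraction of fibers")
            ax.legend()
            fig.tight_layout()
            fig.savefig(out_dir / "cohort_histograms.png", dpi=120)
            plt.close(fig)
    return report
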