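# myofiberquant

Whole-slide quantification of skeletal muscle histology: overlap-tiled
instance segmentation with provably exactly-once mask reconstruction,
random-forest artifact filtering, per-fiber morphometry (minimal Feret
diameter, centrally nucleated fibers) and IoU-based segmentation
evaluation — plus a synthetic H&E section generator with planted ground
truth so every stage can be verified end to end.

## The problem

Preclinical studies of muscular dystrophy and gene-therapy dose response
are read out on transverse H&E sections of skeletal muscle. The three
standard indicators are all per-fiber quantities aggregated over thousands
of fibers per section:

* **minimal Feret diameter** — the minimum caliper width of the fiber
  outline, robust to oblique sectioning; dystrophic muscle shifts smaller
  and broader;
* **variance coefficient (VC)** — SD/mean of diameters; heterogeneity is
  elevated in disease;
* **CNF ratio** — the fraction of Centrally Nucleated Fibers (≥ 1 nucleus
  farther than 2.2 µm from the sarcolemma, strictly); elevated CNF marks
  degeneration/regeneration cycling.

Whole-slide images are far larger than any segmentation model's working
field, so sections must be cut into tiles, segmented per tile, and the
per-tile masks reassembled. Naive stitching double-counts fibers in the
overlap strips or truncates fibers at tile borders; both corrupt the
diameter histogram that the biology is read from. This package makes the
reassembly rule explicit and testable:

* tiles of 712 px with 200 px overlap (fibers must be smaller than the
  overlap);
* a mask lying entirely inside a tile's top/left overlap stripe belongs to
  the neighbor and is removed — *unless* it reaches the stripe's inner
  edge row/column, where it is kept (the one-pixel keep band makes the
  kept/removed split exhaustive, so every fiber survives in exactly one
  tile);
* a mask touching the tile's bottom/right border is removed (the neighbor
  sees it whole); both rules are suppressed at the slide edge;
* residual nested duplicates (from the inward-shifted last row/column of
  tiles) are resolved by keeping the larger mask.

Segmentation itself is pluggable (`cellpose` adapter included as an
optional, opaque backend; a ground-truth oracle backend drives all tests),
and obviously-wrong masks over dust, folds and tears are removed by a
random-forest pixel classifier over Gaussian/Laplacian/local-deviation
features.

## Worked example

Generate a synthetic section with known ground truth, run the tiled
pipeline with a deliberately noisy oracle segmenter (5 % dropped masks,
±2 px boundary jitter), and evaluate the reconstruction against the
planted truth:

```python
import numpy as np

from myofiberquant import (
    PerturbationSpec, PipelineConfig, SectionSpec, generate_section,
    match_masks, precision_recall_f1,
)
from myofiberquant.pipeline import run_scene_pipeline

# 1. A synthetic section with known ground truth (1024 x 1024 px, 0.5 um/px)
scene = generate_section(SectionSpec(seed=7, width_px=1024, height_px=1024))
print(f"planted fibers: {len(scene.fiber_polygons)}, "
      f"nuclei: {len(scene.gt_nuclei)}, "
      f"planted CNF fibers: {sum(scene.planted_cnf.values())}")

# 2. Tile (712 px / 200 px overlap), segment with a noisy oracle, reconstruct
noise = PerturbationSpec(drop_rate=0.05, boundary_jitter_px=2)
res = run_scene_pipeline(scene, PipelineConfig(nuclei_mode="oracle"),
                         perturbation=noise)
s = res["summary"]
print(f"reconstructed fibers: {s.n_fibers}")
print(f"mean min-Feret: {s.mean_min_feret_um:.2f} um, VC: {s.vc:.3f}, "
      f"CNF ratio: {s.cnf_ratio:.3f}")

# 3. Evaluate against the planted truth
table = match_masks(res["labels"], scene.gt_fibers)
scores = precision_recall_f1(table)
print(f"precision {scores.precision:.3f}  recall {scores.recall:.3f}  "
      f"F1 {scores.f1:.3f}  ({scores.n_tp} TP / {scores.n_fp} FP / {scores.n_fn} FN)")
print(f"median matched IoU: {np.median([v for _, _, v in table.tp]):.3f}")
```

Output:

```
planted fibers: 74, nuclei: 104, planted CNF fibers: 6
reconstructed fibers: 69
mean min-Feret: 39.78 um, VC: 0.293, CNF ratio: 0.087
precision 1.000  recall 0.932  F1 0.965  (69 TP / 0 FP / 5 FN)
median matched IoU: 0.953
```

With a *noise-free* oracle the same pipeline is exactly lossless
(F1 = 1.0, every per-fiber IoU = 1.0) — that is the package's central
tested invariant, not an approximation.

The same workflow is available from the command line, one subcommand per
stage:

```
myofiberquant simulate --seed 7 --width 1024 --height 1024 --out sim/
myofiberquant tile sim/section.tif --out tiles/
myofiberquant segment tiles/ --backend cellpose
myofiberquant reconstruct tiles/ --out wsi_labels.png
myofiberquant measure wsi_labels.png sim/section.tif --out results
myofiberquant evaluate --pred wsi_labels.png --gt sim/gt_fibers.png --out eval.json
myofiberquant report sections.csv --out cohort/
```

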