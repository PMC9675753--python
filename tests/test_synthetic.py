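"""Synthetic scene generator: determinism, planted truth, perturbations, cohorts."""

import numpy as np
import pytest

from myofiberquant.errors import ParameterError
from myofiberquant.synthetic import (
    ArtifactSpec,
    PerturbationSpec,
    SectionSpec,
    default_cohort_spec,
    generate_cohort,
    generate_section,
    perturb_labels,
)


class TestGenerateSection:
    def test_bitwise_determinism(self):
        spec = SectionSpec(seed=11, width_px=512, height_px=512)
        a = generate_section(spec)
        b = generate_section(spec)
        assert (a.image.pixels == b.image.pixels).all()
        assert a.gt_fibers == b.gt_fibers
        assert a.planted_cnf == b.planted_cnf
        assert len(a.gt_nuclei) == len(b.gt_nuclei)

    def test_seeds_differ(self):
        a = generate_section(SectionSpec(seed=1, width_px=512, height_px=512))
        b = generate_section(SectionSpec(seed=2, width_px=512, height_px=512))
        assert not (a.gt_fibers.labels == b.gt_fibers.labels).all()

    def test_truth_is_consistent(self, small_scene):
        s = small_scene
        labs = set(int(v) for v in s.gt_fibers.label_values())
        assert labs == set(s.fiber_polygons)
        assert labs == set(s.planted_cnf)
        assert labs == set(s.planted_min_feret_um)
        # every nucleus references an existing fiber
        for ann in s.gt_nuclei:
            assert ann.properties["fiber_label"] in labs
        # image, labels and artifact mask share the frame
        assert s.image.shape == s.gt_fibers.shape == s.gt_artifacts.shape

    def test_p_central_zero_plants_no_central_nuclei(self):
        scene = generate_section(
            SectionSpec(seed=3, width_px=640, height_px=640, p_central_nucleus=0.0)
        )
        assert not any(scene.planted_cnf.values())
        assert not any(a.properties["central"] for a in scene.gt_nuclei)

    def test_planted_median_tracks_target(self):
        vals = []
        for seed in (1, 2, 3):
            scene = generate_section(SectionSpec(seed=seed, width_px=1280, height_px=1280))
            vals.extend(scene.planted_min_feret_um.values())
        med = float(np.median(vals))
        assert med == pytest.approx(40.0, rel=0.10)

    def test_artifact_fibers_excluded_from_truth(self, small_scene):
        # no ground-truth fiber pixel may lie under an artifact
        overlap = (small_scene.gt_fibers.labels > 0) & small_scene.gt_artifacts
        assert overlap.sum() == 0

    def test_no_artifacts_when_disabled(self, clean_scene):
        assert not clean_scene.gt_artifacts.any()

    def test_max_extent_cap(self):
        scene = generate_section(
            SectionSpec(seed=5, width_px=900, height_px=900, max_extent_px=150)
        )
        from scipy import ndimage

        # the vector maximal Feret extent respects the cap exactly...
        for poly in scene.fiber_polygons.values():
            pts = np.asarray(poly.convex_hull.exterior.coords)
            d2 = ((pts[:, None] - pts[None, :]) ** 2).sum(-1)
            assert np.sqrt(d2.max()) <= 150 + 1e-6
        # ...so each rasterized bounding box stays within cap + 1 px per axis
        for sl in ndimage.find_objects(scene.gt_fibers.labels):
            if sl is None:
                continue
            assert sl[0].stop - sl[0].start <= 151
            assert sl[1].stop - sl[1].start <= 151

    def test_invalid_spec(self):
        with pytest.raises(ParameterError):
            SectionSpec(p_central_nucleus=1.5)
        with pytest.raises(ParameterError):
            SectionSpec(fiber_median_um=-1)

    def test_nuclei_respect_planted_margins(self, small_scene):
        """Peripheral nuclei sit < 1.2 um from the boundary, central > 3.2 um,
        measured on the true vector geometry."""
        px = small_scene.spec.pixel_size_um
        for ann in small_scene.gt_nuclei:
            fiber = small_scene.fiber_polygons[ann.properties["fiber_label"]]
            d_um = fiber.exterior.distance(ann.polygon.exterior) * px
            if ann.properties["central"]:
                assert d_um > 3.2 - 1e-6
            else:
                assert d_um < 1.2 + 1e-6


class TestPerturbations:
    def test_identity(self, small_scene):
        out, log = perturb_labels(small_scene.gt_fibers, PerturbationSpec())
        assert out == small_scene.gt_fibers
        assert log["dropped"] == [] and log["spurious"] == []

    def test_determinism(self, small_scene):
        spec = PerturbationSpec(seed=4, drop_rate=0.3, boundary_jitter_px=2, spurious_rate=5)
        a, la = perturb_labels(small_scene.gt_fibers, spec)
        b, lb = perturb_labels(small_scene.gt_fibers, spec)
        assert a == b and la == lb

    def test_drop_log_matches_labels(self, small_scene):
        out, log = perturb_labels(small_scene.gt_fibers, PerturbationSpec(seed=1, drop_rate=0.4))
        before = set(int(v) for v in small_scene.gt_fibers.label_values())
        after = set(int(v) for v in out.label_values())
        assert after == before - set(log["dropped"])
        # surviving masks are pixel-identical
        for lab in after:
            assert (
                (out.labels == lab) == (small_scene.gt_fibers.labels == lab)
            ).all()

    def test_drop_all(self, small_scene):
        out, log = perturb_labels(small_scene.gt_fibers, PerturbationSpec(drop_rate=1.0))
        assert out.label_values().size == 0
        assert len(log["dropped"]) == len(small_scene.gt_fibers.label_values())

    def test_spurious_on_background_only(self, small_scene):
        gt = small_scene.gt_fibers
        out, log = perturb_labels(gt, PerturbationSpec(seed=2, spurious_rate=20))
        assert len(log["spurious"]) > 0
        for lab in log["spurious"]:
            mask = out.labels == lab
            assert mask.any()
            assert (gt.labels[mask] == 0).all()

    def test_jitter_changes_boundaries_not_count(self, small_scene):
        gt = small_scene.gt_fibers
        out, log = perturb_labels(gt, PerturbationSpec(seed=9, boundary_jitter_px=2))
        assert set(out.label_values()) == set(gt.label_values())
        assert not (out.labels == gt.labels).all()
        # dilation happens only into background: no label steals another's pixels
        both = (gt.labels > 0) & (out.labels > 0)
        assert (gt.labels[both] == out.labels[both]).all()

    def test_split_creates_fresh_label(self, small_scene):
        gt = small_scene.gt_fibers
        out, log = perturb_labels(gt, PerturbationSpec(seed=6, split_rate=0.5))
        assert log["split"]
        for old, new in log["split"].items():
            assert (out.labels == new).any()
            union = (out.labels == old) | (out.labels == new)
            assert (union == (gt.labels == old)).all()

    def test_merge_absorbs_neighbor(self, small_scene):
        gt = small_scene.gt_fibers
        out, log = perturb_labels(gt, PerturbationSpec(seed=6, merge_rate=0.3))
        assert log["merged"]
        for keeper, gone_list in log["merged"].items():
            for gone in gone_list:
                assert not (out.labels == gone).any()
                assert (out.labels[gt.labels == gone] == keeper).all()

    def test_invalid_rates(self):
        with pytest.raises(ParameterError):
            PerturbationSpec(drop_rate=1.5)
        with pytest.raises(ParameterError):
            PerturbationSpec(boundary_jitter_px=-1)


class TestCohorts:
    def test_bookkeeping_and_determinism(self):
        spec = default_cohort_spec(master_seed=3, n_sections=1, width_px=512, height_px=512)
        cohort = generate_cohort(spec)
        assert [g for g, _ in cohort] == ["WT", "dose_high", "dose_mid", "dose_low", "KO"]
        again = generate_cohort(spec)
        for (g1, s1), (g2, s2) in zip(cohort, again):
            assert g1 == g2
            assert (s1.image.pixels == s2.image.pixels).all()

    def test_sections_within_group_differ(self):
        spec = default_cohort_spec(master_seed=1, n_sections=2, width_px=512, height_px=512)
        cohort = generate_cohort(spec)
        wt = [s for g, s in cohort if g == "WT"]
        assert len(wt) == 2
        assert not (wt[0].gt_fibers.labels == wt[1].gt_fibers.labels).all()

    def test_group_overrides_applied(self):
        spec = default_cohort_spec(master_seed=0, n_sections=1, width_px=512, height_px=512)
        cohort = dict(generate_cohort(spec))
        assert cohort["WT"].spec.fiber_median_um == 40.0
        assert cohort["KO"].spec.fiber_median_um == 28.0
        assert cohort["KO"].spec.p_central_nucleus == 0.30
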