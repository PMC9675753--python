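"""Minimal Feret diameter, nucleus logic, CNF rule, section summaries."""

import numpy as np
import pytest
from shapely import affinity
from shapely.geometry import Point, Polygon

from myofiberquant.errors import DegenerateGeometryError, EmptySectionError, ParameterError
from myofiberquant.imaging import Annotation, AnnotationSet, LabelImage
from myofiberquant.morphometry import (
    CnfParams,
    FiberMeasurement,
    assign_nuclei_to_fibers,
    classify_cnf,
    detect_nuclei,
    measure_section,
    min_feret_diameter,
    summarize_section,
)


def brute_force_min_feret(polygon, pixel_size_um=1.0, step_deg=0.1):
    """Independent oracle: projection width swept over fixed angle steps."""
    pts = np.asarray(polygon.convex_hull.exterior.coords)[:-1]
    ang = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = np.stack([np.cos(ang), np.sin(ang)], axis=1)  # (A, 2)
    proj = pts @ dirs.T  # (V, A)
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min() * pixel_size_um)


def _regular_polygon(n, radius, cx=0.0, cy=0.0):
    a = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Polygon(np.stack([cx + radius * np.cos(a), cy + radius * np.sin(a)], axis=1))


class TestMinFeret:
    def test_axis_aligned_rectangle(self):
        rect = Polygon([(0, 0), (30, 0), (30, 10), (0, 10)])
        assert min_feret_diameter(rect) == pytest.approx(10.0, abs=1e-12)

    def test_rotated_rectangle(self):
        rect = Polygon([(0, 0), (30, 0), (30, 10), (0, 10)])
        for deg in (17.0, 45.0, 90.0, 123.456):
            r = affinity.rotate(rect, deg, origin="centroid")
            assert min_feret_diameter(r) == pytest.approx(10.0, rel=1e-9)

    def test_square_scaling_and_units(self):
        sq = Polygon([(0, 0), (8, 0), (8, 8), (0, 8)])
        assert min_feret_diameter(sq) == pytest.approx(8.0)
        assert min_feret_diameter(sq, pixel_size_um=0.5) == pytest.approx(4.0)

    def test_equilateral_triangle_height(self):
        tri = Polygon([(0, 0), (2, 0), (1, np.sqrt(3))])
        assert min_feret_diameter(tri) == pytest.approx(np.sqrt(3), rel=1e-12)

    def test_hexagon(self):
        # regular hexagon with circumradius 10: width across flats = 10*sqrt(3)
        hexa = _regular_polygon(6, 10.0)
        assert min_feret_diameter(hexa) == pytest.approx(10 * np.sqrt(3), rel=1e-9)

    def test_concave_polygon_uses_hull(self):
        # an L-shape: the minimal width is attained flush against the
        # hull's hypotenuse edge, at distance 14/sqrt(2) from the far corner
        ell = Polygon([(0, 0), (10, 0), (10, 4), (4, 4), (4, 10), (0, 10)])
        assert min_feret_diameter(ell) == pytest.approx(14 / np.sqrt(2), rel=1e-12)
        assert min_feret_diameter(ell) == pytest.approx(
            min_feret_diameter(ell.convex_hull), rel=1e-12
        )

    def test_against_brute_force_random(self):
        rng = np.random.default_rng(99)
        worst = 0.0
        for _ in range(60):
            n = int(rng.integers(5, 14))
            pts = rng.normal(size=(n, 2)) * rng.uniform(5, 40)
            poly = Polygon(pts).convex_hull
            if poly.geom_type != "Polygon" or poly.area < 1:
                continue
            exact = min_feret_diameter(poly)
            swept = brute_force_min_feret(poly)
            # the exact value can only be <= any sampled width
            assert exact <= swept + 1e-9
            worst = max(worst, abs(exact - swept) / exact)
        assert worst < 0.005

    def test_rotation_invariance_random(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pts = rng.normal(size=(9, 2)) * 20
            poly = Polygon(pts).convex_hull
            base = min_feret_diameter(poly)
            rot = min_feret_diameter(affinity.rotate(poly, float(rng.uniform(0, 360))))
            assert rot == pytest.approx(base, rel=5e-3)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            min_feret_diameter(Polygon([(0, 0), (1, 1), (2, 2), (3, 3)]))


class TestCnfRule:
    def test_concentric_circles_central(self):
        # fiber radius 20 um, nucleus radius 3 um, gap 17 um > 2.2 -> central
        px = 0.5
        fiber = _regular_polygon(128, 20.0 / px)
        nucleus = _regular_polygon(64, 3.0 / px)
        assert classify_cnf(fiber, nucleus, px) is True

    def test_touching_boundary_peripheral(self):
        px = 0.5
        fiber = _regular_polygon(128, 20.0 / px)
        # nucleus centre placed so its boundary touches the fiber boundary (d = 0)
        r_nuc = 3.0 / px
        inradius = (20.0 / px) * np.cos(np.pi / 128)
        nucleus = _regular_polygon(64, r_nuc, cx=inradius - r_nuc, cy=0.0)
        assert classify_cnf(fiber, nucleus, px) is False

    def test_distance_exactly_at_threshold_is_peripheral(self):
        # construct boundary-to-boundary distance of exactly 2.2 um with squares
        px = 1.0
        fiber = Polygon([(0, 0), (40, 0), (40, 40), (0, 40)])
        nucleus = Polygon([(2.2, 10), (7.2, 10), (7.2, 15), (2.2, 15)])
        assert classify_cnf(fiber, nucleus, px) is False  # strict: 2.2 > 2.2 fails
        assert classify_cnf(fiber, nucleus, px, CnfParams(strict=False)) is True

    def test_just_inside_threshold(self):
        px = 1.0
        fiber = Polygon([(0, 0), (40, 0), (40, 40), (0, 40)])
        nucleus = Polygon([(2.21, 10), (7.21, 10), (7.21, 15), (2.21, 15)])
        assert classify_cnf(fiber, nucleus, px) is True

    def test_centroid_statistic(self):
        px = 1.0
        fiber = Polygon([(0, 0), (40, 0), (40, 40), (0, 40)])
        # nucleus boundary 1 um from fiber edge but centroid 3.5 um away
        nucleus = Polygon([(1, 10), (6, 10), (6, 15), (1, 15)])
        assert classify_cnf(fiber, nucleus, px) is False
        assert classify_cnf(fiber, nucleus, px, CnfParams(distance_statistic="centroid")) is True

    def test_invalid_params(self):
        with pytest.raises(ParameterError):
            CnfParams(central_distance_um=0)
        with pytest.raises(ParameterError):
            CnfParams(distance_statistic="max")

    def test_planted_flags_recovered(self, small_scene):
        """Ground-truth geometry + planted nuclei: the classifier must agree
        with every planted central/peripheral flag (construction leaves
        >1 um of margin around the threshold)."""
        px = small_scene.spec.pixel_size_um
        mism = 0
        for ann in small_scene.gt_nuclei:
            fiber = small_scene.fiber_polygons[ann.properties["fiber_label"]]
            got = classify_cnf(fiber, ann.polygon, px)
            mism += got != ann.properties["central"]
        assert mism == 0


class TestNuclei:
    def test_assignment_by_centroid(self):
        arr = np.zeros((20, 20), dtype=np.int32)
        arr[2:10, 2:10] = 1
        arr[12:18, 12:18] = 2
        nuclei = AnnotationSet(
            [
                Annotation(_regular_polygon(16, 2.0, 5, 5), "nucleus"),
                Annotation(_regular_polygon(16, 2.0, 15, 15), "nucleus"),
                Annotation(_regular_polygon(16, 1.0, 10.5, 2.0), "nucleus"),  # background
            ]
        )
        out = assign_nuclei_to_fibers(nuclei, LabelImage(arr))
        assert out == {0: 1, 1: 2, 2: None}

    def test_detector_on_blank_tissue(self):
        from myofiberquant.imaging import CalibratedImage

        arr = np.empty((64, 64, 3), dtype=np.uint8)
        arr[:] = (226, 148, 158)  # cytoplasm pink, no hematoxylin
        assert len(detect_nuclei(CalibratedImage(arr, 0.5))) == 0

    def test_detector_recall_on_scene(self, small_scene):
        detected = detect_nuclei(small_scene.image)
        planted = small_scene.gt_nuclei
        assert len(planted) > 0
        hits = 0
        centroids = [d.polygon.centroid for d in detected]
        for ann in planted:
            c = ann.polygon.centroid
            if any(c.distance(dc) < 6 for dc in centroids):
                hits += 1
        assert hits / len(planted) > 0.9

    def test_detector_precision_on_scene(self, small_scene):
        detected = detect_nuclei(small_scene.image)
        planted = [a.polygon.centroid for a in small_scene.gt_nuclei]
        false_hits = 0
        for d in detected:
            c = d.polygon.centroid
            if not any(c.distance(p) < 8 for p in planted):
                false_hits += 1
        assert false_hits / max(len(detected), 1) < 0.15


class TestSectionSummary:
    def _m(self, lab, mf, cnf=False):
        return FiberMeasurement(lab, mf, 100.0, (0.0, 0.0), 1, int(cnf))

    def test_two_fiber_example(self):
        s = summarize_section([self._m(1, 10.0), self._m(2, 20.0, cnf=True)])
        assert s.n_fibers == 2
        assert s.cnf_ratio == pytest.approx(0.5)
        assert s.mean_min_feret_um == pytest.approx(15.0)
        # population SD of {10, 20} = 5 -> VC = 1/3
        assert s.vc == pytest.approx(1 / 3)
        assert s.histogram[2] == 1 and s.histogram[4] == 1
        assert s.n_nonempty_classes == 2
        assert s.n_overflow == 0

    def test_right_open_bins(self):
        # 5.0 falls in [5,10), 4.999 in [0,5)
        s = summarize_section([self._m(1, 5.0), self._m(2, 4.999)])
        assert s.histogram[0] == 1 and s.histogram[1] == 1

    def test_overflow_counted_separately(self):
        s = summarize_section([self._m(1, 120.0), self._m(2, 30.0)])
        assert s.n_overflow == 1
        assert s.histogram.sum() == 1

    def test_sample_sd_option(self):
        s = summarize_section(
            [self._m(1, 10.0), self._m(2, 20.0)], population_sd=False
        )
        assert s.vc == pytest.approx(np.sqrt(50.0) / 15.0)

    def test_empty_section_error(self):
        with pytest.raises(EmptySectionError):
            summarize_section([])

    def test_measure_section_against_planted(self, small_scene):
        ms = measure_section(
            small_scene.gt_fibers,
            small_scene.spec.pixel_size_um,
            nuclei=small_scene.gt_nuclei,
        )
        planted = small_scene.planted_min_feret_um
        assert len(ms) == len(planted)
        for m in ms:
            # raster bound on the planted vector value: within a pixel or so
            assert m.min_feret_um == pytest.approx(
                planted[m.fiber_label], abs=2 * small_scene.spec.pixel_size_um
            )
        # CNF flags agree with the planted truth
        cnf_truth = small_scene.planted_cnf
        mismatches = sum(m.is_cnf != cnf_truth[m.fiber_label] for m in ms)
        assert mismatches == 0
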