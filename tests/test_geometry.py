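"""Chord-and-angle measurements on analytic polygons."""

import math

import numpy as np
import pytest
from shapely.geometry import LineString, Polygon

from ggnshape import (
    BiEllipseParams,
    Chord,
    DegenerateShapeError,
    GeometryError,
    PlanarContour,
    bia_sma_ratio,
    longest_diameter,
    make_biellipse_polygon,
    perpendicular_diameter,
    polygon_area,
    quadrilateral_angles,
    shape_features_from_contour,
)
from ggnshape.geometry import resample_contour

from conftest import random_biellipse_params

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def regular_polygon(n, r=1.0):
    th = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


class TestPolygonArea:
    def test_unit_square(self):
        assert polygon_area(PlanarContour(UNIT_SQUARE)) == pytest.approx(1.0)

    def test_orientation_invariant(self):
        assert polygon_area(PlanarContour(UNIT_SQUARE[::-1])) == pytest.approx(1.0)

    def test_biellipse_half_ellipse_areas(self):
        contour, _ = make_biellipse_polygon(BiEllipseParams(6, 4, 3), n_vertices=720)
        expected = math.pi * 3 * (6 + 4) / 2  # two half-ellipses
        assert polygon_area(contour) == pytest.approx(expected, rel=1e-3)

    def test_rejects_too_few_vertices(self):
        with pytest.raises(GeometryError):
            PlanarContour(np.array([[0.0, 0.0], [1.0, 0.0]]))


class TestLongestDiameter:
    def test_square_diagonal(self):
        c = PlanarContour(2.0 * UNIT_SQUARE)
        assert longest_diameter(c).length == pytest.approx(2 * math.sqrt(2))

    def test_biellipse_joined_major_axis(self, canonical_polygon):
        contour, truth = canonical_polygon
        ld = longest_diameter(contour)
        assert ld.length == pytest.approx(truth.LD, rel=1e-4)
        xs = sorted([ld.p1[0], ld.p2[0]])
        assert xs[0] == pytest.approx(-6.0, abs=1e-3)
        assert xs[1] == pytest.approx(4.0, abs=1e-3)

    def test_matches_brute_force_pair_search(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            params = random_biellipse_params(rng)
            contour, _ = make_biellipse_polygon(params, n_vertices=150)
            v = contour.vertices
            d = np.linalg.norm(v[:, None, :] - v[None, :, :], axis=-1)
            ld = longest_diameter(contour, resample=False)
            assert ld.length == pytest.approx(d.max(), abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(11)
        base, _ = make_biellipse_polygon(BiEllipseParams(6, 4, 3), n_vertices=500)
        th = math.radians(37.0)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        moved = PlanarContour(base.vertices @ rot.T + [12.3, -4.5])
        assert longest_diameter(moved).length == pytest.approx(
            longest_diameter(base).length, abs=1e-9
        )


class TestPerpendicularDiameter:
    def test_biellipse_shared_minor_axis(self, canonical_polygon):
        contour, truth = canonical_polygon
        ld = longest_diameter(contour)
        pd_ = perpendicular_diameter(contour, ld)
        assert pd_.length == pytest.approx(truth.PD, rel=1e-3)
        # the maximal perpendicular chord sits at the half-ellipse junction
        assert abs(pd_.p1[0]) < 0.15 and abs(pd_.p2[0]) < 0.15
        assert sorted([pd_.p1[1], pd_.p2[1]]) == pytest.approx([-3.0, 3.0], abs=0.01)

    def test_circle_pd_equals_ld(self):
        c = PlanarContour(regular_polygon(720, r=5.0))
        ld = longest_diameter(c)
        pd_ = perpendicular_diameter(c, ld)
        assert pd_.length == pytest.approx(ld.length, rel=1e-3)

    def test_rectangle_matches_shapely_sweep_oracle(self):
        rect = PlanarContour(np.array([[0, 0], [4, 0], [4, 2], [0, 2]], float))
        ld = longest_diameter(rect)
        pd_ = perpendicular_diameter(rect, ld)
        # independent oracle: shapely clipping on a 10x finer sweep
        poly = Polygon(rect.vertices)
        a, b = np.asarray(ld.p1), np.asarray(ld.p2)
        u = (b - a) / np.linalg.norm(b - a)
        n = np.array([-u[1], u[0]])
        best = 0.0
        for t in np.linspace(0, 1, 5001)[1:-1]:
            foot = a + t * (b - a)
            line = LineString([foot - 20 * n, foot + 20 * n])
            seg = line.intersection(poly)
            best = max(best, seg.length)
        assert pd_.length == pytest.approx(best, rel=1e-2)
        assert pd_.length <= ld.length

    def test_fine_sweep_agreement(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            contour, _ = make_biellipse_polygon(
                random_biellipse_params(rng), n_vertices=500
            )
            ld = longest_diameter(contour)
            coarse = perpendicular_diameter(contour, ld, n_steps=500)
            fine = perpendicular_diameter(contour, ld, n_steps=5000)
            assert coarse.length == pytest.approx(fine.length, rel=1e-2)

    def test_never_longer_than_ld(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            contour, _ = make_biellipse_polygon(
                random_biellipse_params(rng), n_vertices=360
            )
            ld = longest_diameter(contour)
            pd_ = perpendicular_diameter(contour, ld)
            assert pd_.length <= ld.length + 1e-9


class TestQuadrilateralAngles:
    def test_rhombus_symmetric(self):
        ld = Chord((-1.0, 0.0), (1.0, 0.0))
        pd_ = Chord((0.0, 1.0), (0.0, -1.0))
        ang = quadrilateral_angles(ld, pd_)
        assert ang.angle_A == pytest.approx(90.0)
        assert ang.angle_B == pytest.approx(90.0)
        assert ang.ratio == pytest.approx(1.0)

    def test_kite_closed_form(self):
        # vertex angles are atan(CO/AO) + atan(OD/AO) at each LD endpoint
        ld = Chord((-1.0, 0.0), (2.0, 0.0))
        pd_ = Chord((0.0, 1.0), (0.0, -1.0))
        ang = quadrilateral_angles(ld, pd_)
        assert ang.angle_A == pytest.approx(2 * math.degrees(math.atan(1.0)), abs=1e-9)
        assert ang.angle_B == pytest.approx(
            2 * math.degrees(math.atan(0.5)), abs=1e-9
        )
        assert ang.BiA == pytest.approx(90.0)
        assert ang.SmA == pytest.approx(53.1301, abs=1e-4)
        assert ang.ratio == pytest.approx(90.0 / math.degrees(2 * math.atan(0.5)))

    def test_biellipse_big_angle_at_near_endpoint(self, canonical_truth):
        # the LD endpoint nearer the chord crossing carries the bigger angle
        ld = Chord((-6.0, 0.0), (4.0, 0.0))
        pd_ = Chord((0.0, 3.0), (0.0, -3.0))
        ang = quadrilateral_angles(ld, pd_)
        assert ang.BiA == pytest.approx(canonical_truth.BiA, abs=1e-4)
        assert ang.SmA == pytest.approx(canonical_truth.SmA, abs=1e-4)
        assert ang.ratio == pytest.approx(1.3879, abs=1e-4)

    def test_label_swap_invariance(self):
        ld = Chord((-6.0, 0.0), (4.0, 0.0))
        pd_ = Chord((0.0, 3.0), (0.0, -3.0))
        ref = quadrilateral_angles(ld, pd_)
        for ld2, pd2 in [
            (Chord(ld.p2, ld.p1), pd_),
            (ld, Chord(pd_.p2, pd_.p1)),
            (Chord(ld.p2, ld.p1), Chord(pd_.p2, pd_.p1)),
        ]:
            ang = quadrilateral_angles(ld2, pd2)
            assert ang.BiA == pytest.approx(ref.BiA)
            assert ang.SmA == pytest.approx(ref.SmA)

    def test_disjoint_chords_rejected(self):
        ld = Chord((0.0, 0.0), (1.0, 0.0))
        pd_ = Chord((5.0, 1.0), (5.0, -1.0))
        with pytest.raises(GeometryError):
            quadrilateral_angles(ld, pd_)


class TestBiaSmaRatio:
    def test_reported_measurement_example(self):
        # 77.03 deg over 60.55 deg, the worked nodule measurement
        assert bia_sma_ratio(77.03, 60.55) == pytest.approx(1.2722, abs=5e-5)

    def test_equal_angles(self):
        assert bia_sma_ratio(90.0, 90.0) == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(GeometryError):
            bia_sma_ratio(50.0, 60.0)
        with pytest.raises(GeometryError):
            bia_sma_ratio(60.0, 0.0)


class TestShapeFeaturesFromContour:
    def test_recovers_generator_ground_truth(self, canonical_polygon):
        contour, truth = canonical_polygon
        f = shape_features_from_contour(contour)
        assert f.LD == pytest.approx(truth.LD, rel=1e-3)
        assert f.PD == pytest.approx(truth.PD, rel=1e-3)
        assert f.BiA == pytest.approx(truth.BiA, abs=1.0)
        assert f.SmA == pytest.approx(truth.SmA, abs=1.0)
        assert f.ld_pd_ratio >= 1.0 and f.bia_sma_ratio >= 1.0

    def test_uniform_scaling(self):
        contour, _ = make_biellipse_polygon(BiEllipseParams(6, 4, 3), n_vertices=500)
        f1 = shape_features_from_contour(contour)
        scaled = PlanarContour(contour.vertices * 2.5)
        f2 = shape_features_from_contour(scaled)
        assert f2.LD == pytest.approx(2.5 * f1.LD, rel=1e-6)
        assert f2.PD == pytest.approx(2.5 * f1.PD, rel=1e-3)
        assert f2.MA == pytest.approx(2.5**2 * f1.MA, rel=1e-6)
        assert f2.ld_pd_ratio == pytest.approx(f1.ld_pd_ratio, rel=1e-3)
        assert f2.bia_sma_ratio == pytest.approx(f1.bia_sma_ratio, rel=1e-3)

    def test_vertex_order_reversal(self, canonical_polygon):
        contour, _ = canonical_polygon
        f1 = shape_features_from_contour(contour)
        f2 = shape_features_from_contour(PlanarContour(contour.vertices[::-1]))
        assert f2.MA == pytest.approx(f1.MA, abs=1e-9)
        # reversal changes the resampling start direction: equal to 1e-6
        assert f2.LD == pytest.approx(f1.LD, abs=1e-6)


def test_resample_preserves_shape():
    v = resample_contour(2.0 * UNIT_SQUARE, n=400)
    assert len(v) == 400
    area = polygon_area(PlanarContour(v))
    assert area == pytest.approx(4.0, rel=1e-3)
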