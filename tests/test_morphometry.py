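"""Geometric and convex-hull features against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest

from gliamorph.core import PixelCalibration
from gliamorph.morphometry import (
    DegenerateHullError,
    HullGeometry,
    bounding_circle,
    circularity,
    convex_hull,
    density_roughness,
    hull_metrics,
    hull_of_points,
    measure_area_perimeter,
    transformation_index,
)
from gliamorph.synthetic import generate_silhouette, make_reference_shape, slightly_ramified_params

from conftest import random_pixel_mask

SQRT2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_hull_vertices(points: np.ndarray) -> set[tuple[float, float]]:
    """O(n³) hull: (i, j) is a CCW hull edge iff every other point is strictly
    left of it, or collinear and between the endpoints."""
    pts = np.asarray(points, float)
    vertices: set[tuple[float, float]] = set()
    n = len(pts)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            ok = True
            for k in range(n):
                if k in (i, j):
                    continue
                r = pts[k] - pts[i]
                cross = d[0] * r[1] - d[1] * r[0]
                if cross < 0:
                    ok = False
                    break
                if cross == 0:  # collinear: must lie between i and j
                    t = np.dot(r, d) / np.dot(d, d)
                    if not 0 < t < 1:
                        ok = False
                        break
            if ok:
                vertices.add(tuple(pts[i]))
                vertices.add(tuple(pts[j]))
    return vertices


def brute_force_min_circle(points: np.ndarray) -> float:
    """Smallest enclosing circle radius by testing all pairs and triples."""
    pts = np.asarray(points, float)
    n = len(pts)
    best = np.inf

    def covers(c, r):
        return np.all(np.hypot(*(pts - c).T) <= r + 1e-12)

    for i in range(n):
        for j in range(i + 1, n):
            c = (pts[i] + pts[j]) / 2
            r = np.linalg.norm(pts[i] - c)
            if r < best and covers(c, r):
                best = r
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                ax, ay = pts[i]
                bx, by = pts[j]
                cx, cy = pts[k]
                d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
                if abs(d) < 1e-12:
                    continue
                ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
                      + (cx**2 + cy**2) * (ay - by)) / d
                uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
                      + (cx**2 + cy**2) * (bx - ax)) / d
                c = np.array([ux, uy])
                r = np.linalg.norm(pts[i] - c)
                if r < best and covers(c, r):
                    best = r
    return best


# ---------------------------------------------------------------------------
# area / perimeter / circularity


class TestAreaPerimeter:
    def test_square_area_exact_perimeter_close(self):
        sq = make_reference_shape("square", 10)
        area, perim = measure_area_perimeter(sq)
        assert area == 100.0
        assert perim == pytest.approx(40.0, rel=0.05)

    def test_calibration_scaling(self):
        sq = make_reference_shape("square", 10)
        area, perim = measure_area_perimeter(sq, PixelCalibration(0.5))
        assert area == 25.0
        a1, p1 = measure_area_perimeter(sq, PixelCalibration(1.0))
        assert perim == pytest.approx(0.5 * p1, rel=1e-12)

    def test_disk_matches_analytic_circle(self):
        disk = make_reference_shape("disk", 100)
        area, perim = measure_area_perimeter(disk)
        assert area == pytest.approx(math.pi * 100**2, rel=0.01)
        assert perim == pytest.approx(2 * math.pi * 100, rel=0.02)

    def test_large_square_approaches_pixel_edge_perimeter(self):
        sq = make_reference_shape("square", 60)
        _, perim = measure_area_perimeter(sq)
        assert perim == pytest.approx(240.0, rel=0.01)

    def test_empty_mask(self):
        with pytest.raises(ValueError):
            measure_area_perimeter(np.zeros((5, 5), bool))


class TestCircularityTI:
    def test_ideal_circle_is_one(self):
        r = 100.0
        assert circularity(math.pi * r**2, 2 * math.pi * r) == pytest.approx(1.0)
        assert transformation_index(math.pi * r**2, 2 * math.pi * r) == pytest.approx(1.0)

    def test_square_closed_form(self):
        assert circularity(100.0, 40.0) == pytest.approx(math.pi / 4)
        assert transformation_index(100.0, 40.0) == pytest.approx(4 / math.pi)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_reciprocal_identity(self, seed):
        """TI·circularity = 1 for any measured silhouette."""
        sil = generate_silhouette(slightly_ramified_params(), seed=seed, crop_size=128)
        area, perim = measure_area_perimeter(sil)
        assert circularity(area, perim) * transformation_index(area, perim) == (
            pytest.approx(1.0, abs=1e-12)
        )

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            circularity(1.0, 0.0)
        with pytest.raises(ValueError):
            transformation_index(0.0, 1.0)


# ---------------------------------------------------------------------------
# convex hull


class TestConvexHull:
    def test_plus_polyomino_corner_hull(self):
        """Hull of the 5-cell plus (unit cells, outer corners): area 7,
        perimeter 4 + 4√2."""
        plus = make_reference_shape("plus", 1)
        hull = convex_hull(plus, points="corners")
        assert hull.area == pytest.approx(7.0, abs=1e-12)
        assert hull.perimeter == pytest.approx(4 + 4 * SQRT2, abs=1e-12)

    def test_square_corner_hull_is_square(self):
        sq = make_reference_shape("square", 10)
        hull = convex_hull(sq, points="corners")
        assert hull.area == pytest.approx(100.0, abs=1e-12)
        assert hull.perimeter == pytest.approx(40.0, abs=1e-12)

    def test_hull_contains_every_pixel_center(self):
        rng = np.random.default_rng(5)
        mask = random_pixel_mask(rng)
        hull = convex_hull(mask, points="centers")
        from shapely.geometry import Point, Polygon

        poly = Polygon(hull.vertices).buffer(1e-9)
        rr, cc = np.nonzero(mask)
        assert all(poly.contains(Point(r, c)) for r, c in zip(rr, cc))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        """Exact vertex agreement with the O(n³) supporting-edge oracle."""
        rng = np.random.default_rng(1000 + seed)
        mask = random_pixel_mask(rng, n_pixels=30)
        hull = convex_hull(mask, points="centers")
        rr, cc = np.nonzero(mask)
        oracle = brute_force_hull_vertices(np.column_stack([rr, cc]))
        ours = {tuple(v) for v in hull.vertices}
        assert ours == oracle

    def test_collinear_mask_degenerate_with_centers(self):
        mask = np.zeros((10, 10), bool)
        mask[4, 2:8] = True
        with pytest.raises(DegenerateHullError):
            convex_hull(mask, points="centers")
        # corner hull of the same 1-px line is a valid 1xN rectangle
        hull = convex_hull(mask, points="corners")
        assert hull.area == pytest.approx(6.0)

    def test_empty_mask(self):
        with pytest.raises(DegenerateHullError):
            convex_hull(np.zeros((4, 4), bool))


class TestHullMetrics:
    def test_square_vertices(self):
        a = 6.0
        hull = hull_of_points(np.array([[0, 0], [0, a], [a, a], [a, 0]]))
        m = hull_metrics(hull)
        assert m.mean_radius == pytest.approx(a / SQRT2)
        assert m.max_span == pytest.approx(a * SQRT2)
        assert m.max_min_radii == pytest.approx(1.0)  # all corner radii equal
        assert m.span_ratio == pytest.approx(SQRT2)

    def test_rectangle_span_and_ratio(self):
        hull = hull_of_points(np.array([[0, 0], [0, 40], [20, 40], [20, 0]]))
        m = hull_metrics(hull)
        assert m.max_span == pytest.approx(math.sqrt(2000))
        assert m.span_ratio == pytest.approx(math.sqrt(2000) / 20)

    def test_fine_polygon_circle_circularity(self):
        ang = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        hull = hull_of_points(np.column_stack([np.cos(ang), np.sin(ang)]) * 100)
        m = hull_metrics(hull)
        assert m.hull_circularity == pytest.approx(1.0, abs=1e-4)
        assert m.max_min_radii == pytest.approx(1.0, abs=1e-6)

    def test_hull_circularity_bounds_cell_circularity(self):
        """The hull is rounder than the cell: hull_circularity >= circularity."""
        for seed in range(5):
            sil = generate_silhouette(
                slightly_ramified_params(), seed=100 + seed, crop_size=128
            )
            area, perim = measure_area_perimeter(sil)
            hull = convex_hull(sil)
            assert hull_metrics(hull).hull_circularity >= circularity(area, perim)


class TestBoundingCircle:
    def test_three_point_example(self):
        hull = hull_of_points(np.array([[0, 0], [2, 0], [1, 1]]))
        assert bounding_circle(hull) == pytest.approx(2.0, abs=1e-9)

    def test_square_circumcircle(self):
        a = 5.0
        hull = hull_of_points(np.array([[0, 0], [0, a], [a, a], [a, 0]]))
        assert bounding_circle(hull) == pytest.approx(a * SQRT2, abs=1e-9)

    def test_equilateral_triangle(self):
        tri = np.array([[0, 0], [1, 0], [0.5, math.sqrt(3) / 2]])
        assert bounding_circle(hull_of_points(tri)) == pytest.approx(2 / math.sqrt(3), abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pair_triple_oracle(self, seed):
        rng = np.random.default_rng(2000 + seed)
        pts = rng.random((10, 2)) * 50
        oracle = brute_force_min_circle(pts)
        assert bounding_circle(pts) / 2 == pytest.approx(oracle, abs=1e-9)

    def test_jung_inequality(self):
        """max_span <= bounding diameter <= (2/√3)·max_span for every hull."""
        for seed in range(10):
            rng = np.random.default_rng(3000 + seed)
            hull = hull_of_points(rng.random((12, 2)) * 30)
            span = hull_metrics(hull).max_span
            diameter = bounding_circle(hull)
            assert span <= diameter + 1e-9
            assert diameter <= 2 / math.sqrt(3) * span + 1e-9


class TestDensityRoughness:
    def test_convex_square_is_unity(self):
        sq = make_reference_shape("square", 60)
        area, perim = measure_area_perimeter(sq)
        dens, rough = density_roughness(area, perim, convex_hull(sq))
        assert dens == pytest.approx(1.0, abs=1e-12)
        assert rough == pytest.approx(1.0, rel=0.02)

    def test_plus_polyomino(self):
        plus = make_reference_shape("plus", 20)
        area, perim = measure_area_perimeter(plus)
        dens, rough = density_roughness(area, perim, convex_hull(plus))
        assert dens == pytest.approx(5 / 7, rel=0.02)
        assert rough == pytest.approx(12 / (4 + 4 * SQRT2), rel=0.02)

    def test_spiky_star_strictly_concave(self):
        star = make_reference_shape("spiky_star", 60)
        area, perim = measure_area_perimeter(star)
        dens, rough = density_roughness(area, perim, convex_hull(star))
        assert dens < 0.8
        assert rough > 1.5

    def test_density_bounded_roughness_lower_bound(self):
        for seed in range(8):
            sil = generate_silhouette(
                slightly_ramified_params(), seed=200 + seed, crop_size=128
            )
            area, perim = measure_area_perimeter(sil)
            dens, rough = density_roughness(area, perim, convex_hull(sil))
            assert 0 < dens <= 1 + 1e-12
            assert rough >= 0.95  # perimeter discretisation tolerance


class TestScaleInvariance:
    def test_dimensionless_features_calibration_exact(self):
        sil = generate_silhouette(slightly_ramified_params(), seed=9, crop_size=128)
        vals = {}
        for mpp in (1.0, 0.37):
            cal = PixelCalibration(mpp)
            area, perim = measure_area_perimeter(sil, cal)
            hull = convex_hull(sil, cal)
            dens, rough = density_roughness(area, perim, hull)
            vals[mpp] = (
                circularity(area, perim),
                transformation_index(area, perim),
                hull_metrics(hull).hull_circularity,
                hull_metrics(hull).span_ratio,
                dens,
                rough,
            )
        assert vals[1.0] == pytest.approx(vals[0.37], rel=1e-9)

    def test_upsampling_stability(self):
        """2x nearest-neighbour upsampling leaves area/hull-derived
        dimensionless features stable to 5 %.  Perimeter-derived features
        get a looser 15 % band: upsampling turns one-pixel staircase
        artefacts into genuine two-pixel boundary structure, which any
        estimator faithful to reference shapes must measure."""
        sil = generate_silhouette(slightly_ramified_params(), seed=21, crop_size=128)
        big = np.kron(sil.mask, np.ones((2, 2), bool))

        def dimensionless(mask):
            area, perim = measure_area_perimeter(mask)
            hull = convex_hull(mask)
            dens, _ = density_roughness(area, perim, hull)
            m = hull_metrics(hull)
            return np.array([dens, m.span_ratio, m.max_min_radii]), perim

        stable_a, perim_a = dimensionless(sil.mask)
        stable_b, perim_b = dimensionless(big)
        assert np.all(np.abs(stable_a - stable_b) / stable_a < 0.05)
        assert perim_b / (2 * perim_a) == pytest.approx(1.0, abs=0.15)
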