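import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pentadraw.geometry import (
    IDEAL_SPEC,
    PentagonSpec,
    Polygon,
    distort_angles,
    make_regular_polygon,
    pixel_intersection_area,
    place_pentagons,
    polygon_area,
    polygon_intersection_area,
)


def unit_square(offset=(0.0, 0.0)):
    ox, oy = offset
    return Polygon(np.array([[ox, oy], [ox + 1, oy],
                             [ox + 1, oy + 1], [ox, oy + 1]]))


class TestMakeRegularPolygon:
    def test_square_geometry(self):
        p = make_regular_polygon(4, 1.0, (0, 0), 0.0)
        radii = np.linalg.norm(p.vertices, axis=1)
        assert np.allclose(radii, 1.0, atol=1e-9)
        assert np.allclose(p.edge_lengths(), math.sqrt(2), atol=1e-9)

    def test_pentagon_interior_angles(self):
        p = make_regular_polygon(5, 1.0)
        v = p.vertices
        for i in range(5):
            a, b, c = v[i - 1], v[i], v[(i + 1) % 5]
            u, w = a - b, c - b
            cosang = u @ w / (np.linalg.norm(u) * np.linalg.norm(w))
            assert math.degrees(math.acos(cosang)) == pytest.approx(108.0, abs=1e-9)

    def test_scale_linearity(self):
        p1 = make_regular_polygon(5, 1.0)
        p2 = make_regular_polygon(5, 2.0)
        assert p2.edge_lengths().sum() == pytest.approx(
            2 * p1.edge_lengths().sum(), rel=1e-9)

    def test_centroid_at_center(self):
        p = make_regular_polygon(7, 3.0, center=(10.0, -4.0), phase=0.3)
        assert np.allclose(p.centroid, (10.0, -4.0), atol=1e-9)

    @pytest.mark.parametrize("n,r", [(2, 1.0), (5, 0.0), (5, -1.0)])
    def test_invalid_arguments(self, n, r):
        with pytest.raises(ValueError):
            make_regular_polygon(n, r)


class TestDistortAngles:
    def test_zero_scale_is_identity(self, rng):
        p = make_regular_polygon(5, 1.0)
        q = distort_angles(p, 0.0, rng)
        assert np.array_equal(p.vertices, q.vertices)

    def test_deterministic_given_seed(self):
        p = make_regular_polygon(5, 1.0)
        a = distort_angles(p, 0.3, np.random.default_rng(1))
        b = distort_angles(p, 0.3, np.random.default_rng(1))
        assert np.array_equal(a.vertices, b.vertices)

    def test_larger_scale_gives_more_irregular_edges(self):
        # Monte-Carlo ordering: mean edge-length CV grows with scale
        p = make_regular_polygon(5, 1.0)

        def mean_cv(scale):
            cvs = []
            for seed in range(300):
                q = distort_angles(p, scale, np.random.default_rng(seed))
                e = q.edge_lengths()
                cvs.append(e.std() / e.mean())
            return np.mean(cvs)

        assert mean_cv(0.3) > mean_cv(0.1)

    def test_vertex_count_preserved(self, rng):
        p = make_regular_polygon(8, 2.0)
        assert distort_angles(p, 0.25, rng).n == 8

    def test_negative_scale_rejected(self, rng):
        with pytest.raises(ValueError):
            distort_angles(make_regular_polygon(5, 1.0), -0.1, rng)


class TestPolygonArea:
    def test_unit_square(self):
        assert polygon_area(unit_square()) == pytest.approx(1.0, abs=1e-12)

    def test_regular_pentagon_closed_form(self):
        p = make_regular_polygon(5, 1.0)
        expected = 2.5 * math.sin(math.radians(72))
        assert polygon_area(p) == pytest.approx(expected, abs=1e-9)

    def test_orientation_independent(self):
        p = unit_square()
        q = Polygon(p.vertices[::-1])
        assert polygon_area(p) == polygon_area(q)

    def test_matches_rasterization_oracle_on_random_convex_7gon(self, rng):
        p = distort_angles(make_regular_polygon(7, 50.0, (100, 100)), 0.2, rng)
        exact = polygon_area(p)
        approx = pixel_intersection_area(p, p, resolution=2000)
        assert approx == pytest.approx(exact, rel=0.005)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            Polygon(np.array([[0, 0], [0, 0], [1, 1]]))

    @settings(deadline=None, max_examples=25)
    @given(k=st.floats(min_value=0.1, max_value=10))
    def test_scale_equivariance(self, k):
        a = polygon_area(make_regular_polygon(5, 1.0))
        ak = polygon_area(make_regular_polygon(5, k))
        assert ak == pytest.approx(k * k * a, rel=1e-9)


class TestIntersectionArea:
    def test_disjoint_squares(self):
        assert polygon_intersection_area(unit_square(), unit_square((5, 5))) == 0.0

    def test_identical_polygons(self):
        p = make_regular_polygon(6, 2.0)
        assert polygon_intersection_area(p, p) == pytest.approx(
            polygon_area(p), rel=1e-12)

    def test_offset_squares_half_overlap(self):
        got = polygon_intersection_area(unit_square(), unit_square((0.5, 0.0)))
        assert got == pytest.approx(0.5, abs=1e-12)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            a = distort_angles(
                make_regular_polygon(int(rng.integers(3, 9)), 40.0,
                                     tuple(rng.uniform(40, 60, 2))), 0.15, rng)
            b = distort_angles(
                make_regular_polygon(int(rng.integers(3, 9)), 40.0,
                                     tuple(rng.uniform(40, 60, 2))), 0.15, rng)
            ab = polygon_intersection_area(a, b)
            assert ab == pytest.approx(polygon_intersection_area(b, a), rel=1e-9)
            assert ab <= min(polygon_area(a), polygon_area(b)) + 1e-9


class TestPlacePentagons:
    def test_ideal_spec_overlaps_partially(self):
        a, b = place_pentagons(IDEAL_SPEC)
        inter = polygon_intersection_area(a, b)
        assert 0 < inter < min(polygon_area(a), polygon_area(b))

    def test_distance_beyond_radii_sum_is_disjoint(self):
        a, b = place_pentagons(IDEAL_SPEC.with_(distance=1.5))
        assert polygon_intersection_area(a, b) == 0.0

    def test_coincident_congruent_pentagons(self):
        # distance 0 and alignment 0.5: B's phase (pi + pi/5) is a multiple
        # of 2*pi/5, so the two congruent pentagons coincide exactly
        a, b = place_pentagons(IDEAL_SPEC.with_(distance=0.0, alignment=0.5))
        inter = polygon_intersection_area(a, b)
        assert inter == pytest.approx(polygon_area(a), abs=1e-9)

    def test_separation_scales_with_distance(self):
        a1, b1 = place_pentagons(IDEAL_SPEC.with_(distance=0.5))
        a2, b2 = place_pentagons(IDEAL_SPEC.with_(distance=1.0))
        d1 = np.linalg.norm(a1.centroid - b1.centroid)
        d2 = np.linalg.norm(a2.centroid - b2.centroid)
        assert d2 == pytest.approx(2 * d1, rel=1e-9)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PentagonSpec(n_vertices_a=2)
        with pytest.raises(ValueError):
            PentagonSpec(distance=-0.5)
        with pytest.raises(ValueError):
            PentagonSpec(size_equality=0.0)
        with pytest.raises(ValueError):
            PentagonSpec(line_width=0.5)


class TestPixelOracleAgreement:
    def test_exact_intersection_matches_pixel_count(self, rng):
        """Convex pairs: exact clipping vs pixel-count within 1%."""
        for _ in range(30):
            na, nb = rng.integers(3, 11, 2)
            ca = tuple(rng.uniform(80, 120, 2))
            cb = (ca[0] + rng.uniform(10, 50), ca[1] + rng.uniform(-20, 20))
            a = make_regular_polygon(int(na), rng.uniform(40, 70), ca,
                                     rng.uniform(0, 6.28))
            b = make_regular_polygon(int(nb), rng.uniform(40, 70), cb,
                                     rng.uniform(0, 6.28))
            exact = polygon_intersection_area(a, b)
            approx = pixel_intersection_area(a, b, resolution=2000)
            if exact > 1.0:
                assert approx == pytest.approx(exact, rel=0.01)
            else:
                assert approx == pytest.approx(exact, abs=1.0)
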