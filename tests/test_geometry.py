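"""Shape features of single-slice lesion contours: closed-form oracles,
invariances, rasterization cross-check, and the inclusion rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmrd_burden.geometry import (
    OrganLabel,
    Polygon2D,
    equivalent_sphere_diameter,
    filter_lesions,
    lesion_volume,
    polygon_area,
    principal_axis_lengths,
    shape_features,
)
from mmrd_burden.synthetic import generate_lesion_polygon

from .conftest import ellipse_polygon, regular_polygon


def rasterized_area(polygon: Polygon2D, spacing: float = 0.1) -> float:
    """Pixel-counting oracle: fraction of a fine grid inside the contour."""
    from matplotlib.path import Path

    v = polygon.vertices
    x0, y0 = v.min(axis=0) - spacing
    x1, y1 = v.max(axis=0) + spacing
    xs = np.arange(x0, x1, spacing) + spacing / 2
    ys = np.arange(y0, y1, spacing) + spacing / 2
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    ring = np.vstack([v, v[:1]])  # Path(closed=True) ignores the final vertex
    inside = Path(ring, closed=True).contains_points(pts)
    return inside.sum() * spacing**2


class TestPolygonArea:
    @pytest.mark.parametrize(
        "vertices, expected",
        [
            ([(0, 0), (10, 0), (10, 10), (0, 10)], 100.0),
            ([(0, 0), (40, 0), (0, 30)], 600.0),
        ],
    )
    def test_elementary_shapes(self, vertices, expected):
        assert polygon_area(Polygon2D(vertices)) == pytest.approx(expected)

    def test_regular_64gon_closed_form(self):
        # inscribed n-gon area = n/2 * r^2 * sin(2*pi/n)
        n, r = 64, 10.0
        expected = 0.5 * n * r * r * math.sin(2 * math.pi / n)
        assert expected == pytest.approx(313.65, abs=0.01)
        assert polygon_area(regular_polygon(n, r)) == pytest.approx(expected, abs=1e-9)

    def test_vertex_order_irrelevant_for_magnitude(self):
        cw = Polygon2D([(0, 10), (10, 10), (10, 0), (0, 0)])
        assert polygon_area(cw) == pytest.approx(100.0)

    def test_nonconvex_polygon_matches_rasterization(self):
        # an L-shape: signed fan summation must not overcount the notch
        poly = Polygon2D([(0, 0), (20, 0), (20, 10), (10, 10), (10, 20), (0, 20)])
        assert polygon_area(poly) == pytest.approx(300.0)
        assert polygon_area(poly) == pytest.approx(rasterized_area(poly), rel=0.02)

    def test_random_star_polygons_match_rasterization(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            poly = generate_lesion_polygon(
                (0.0, 0.0), rng.uniform(3, 15), rng.uniform(0, 0.4), 24, rng
            )
            assert polygon_area(poly) == pytest.approx(
                rasterized_area(poly), rel=0.02
            )

    def test_degenerate_collinear_polygon_is_zero(self):
        assert polygon_area(Polygon2D([(0, 0), (1, 1), (2, 2), (3, 3)])) == 0.0

    def test_duplicate_vertices_collapsed(self):
        poly = Polygon2D([(0, 0), (0, 0), (10, 0), (10, 10), (0, 10), (0, 0)])
        assert len(poly) == 4
        assert polygon_area(poly) == pytest.approx(100.0)

    def test_fewer_than_three_distinct_vertices_rejected(self):
        with pytest.raises(ValueError):
            Polygon2D([(0, 0), (1, 0), (1, 0), (0, 0)])


class TestPrincipalAxes:
    def test_disk_axes_equal_diameter(self):
        major, minor = principal_axis_lengths(regular_polygon(256, 10.0))
        assert major == pytest.approx(20.0, rel=0.005)
        assert minor == pytest.approx(20.0, rel=0.005)

    def test_ellipse_axes(self):
        major, minor = principal_axis_lengths(ellipse_polygon(30.0, 10.0))
        assert major == pytest.approx(60.0, rel=0.005)
        assert minor == pytest.approx(20.0, rel=0.005)

    def test_square_closed_form(self):
        # uniform square variance w^2/12 -> axis 4w/sqrt(12)
        major, minor = principal_axis_lengths(
            Polygon2D([(0, 0), (10, 0), (10, 10), (0, 10)])
        )
        assert major == pytest.approx(40.0 / math.sqrt(12.0), abs=1e-6)
        assert minor == pytest.approx(40.0 / math.sqrt(12.0), abs=1e-6)

    def test_degenerate_polygon_zero_axes(self):
        assert principal_axis_lengths(Polygon2D([(0, 0), (1, 1), (2, 2)])) == (0.0, 0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        angle=st.floats(0, 2 * math.pi),
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
        s=st.sampled_from([0.5, 2.0, 10.0]),
    )
    def test_invariances_and_scaling(self, seed, angle, dx, dy, s):
        poly = generate_lesion_polygon((0.0, 0.0), 8.0, 0.3, 24, seed)
        f0 = shape_features(poly)
        assert f0.minor_axis <= f0.major_axis
        moved = poly.rotated(angle).translated(dx, dy)
        f1 = shape_features(moved)
        assert f1.surface == pytest.approx(f0.surface, rel=1e-9)
        assert f1.major_axis == pytest.approx(f0.major_axis, rel=1e-9)
        assert f1.minor_axis == pytest.approx(f0.minor_axis, rel=1e-9)
        fs = shape_features(poly.scaled(s))
        assert fs.surface == pytest.approx(f0.surface * s * s, rel=1e-9)
        assert fs.major_axis == pytest.approx(f0.major_axis * s, rel=1e-9)
        assert fs.volume == pytest.approx(f0.volume * s**3, rel=1e-9)


class TestVolume:
    def test_sphere_identity(self):
        # (2/3) * (pi r^2) * (2r) = (4/3) pi r^3
        r = 10.0
        assert lesion_volume(math.pi * r * r, 2 * r) == pytest.approx(
            4.0 / 3.0 * math.pi * r**3, abs=0.01
        )

    @pytest.mark.parametrize("surface, minor, expected", [(0, 5, 0), (100, 3, 200)])
    def test_direct_product(self, surface, minor, expected):
        assert lesion_volume(surface, minor) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            lesion_volume(-1.0, 5.0)
        with pytest.raises(ValueError):
            lesion_volume(5.0, -1.0)

    @pytest.mark.parametrize("n", [128, 256, 512])
    def test_ngon_volume_converges_to_sphere(self, n):
        r = 10.0
        f = shape_features(regular_polygon(n, r))
        assert f.volume == pytest.approx(4.0 / 3.0 * math.pi * r**3, rel=0.01)

    def test_ellipse_phantom(self):
        a, b = 25.0, 12.0
        f = shape_features(ellipse_polygon(a, b, 256))
        assert f.volume == pytest.approx(4.0 / 3.0 * math.pi * a * b * b, rel=0.01)


class TestSphereDiameter:
    def test_90_cm3_rounds_to_5_6(self):
        assert round(equivalent_sphere_diameter(90.0), 1) == 5.6

    def test_unit_sphere(self):
        assert equivalent_sphere_diameter(4.0 / 3.0 * math.pi * 0.5**3) == pytest.approx(1.0)

    def test_zero_and_negative(self):
        assert equivalent_sphere_diameter(0.0) == 0.0
        with pytest.raises(ValueError):
            equivalent_sphere_diameter(-1.0)


class TestFilterRules:
    def test_fixture_retains_exactly_four(self, filter_fixture):
        kept = filter_lesions(filter_fixture)
        assert [m.annotation.lesion_id for m in kept] == ["L1", "L4", "L5", "L6"]

    def test_thresholds_are_strict(self, filter_fixture):
        # sanity on the fixture itself: dropped lesions sit below threshold
        by_id = {m.annotation.lesion_id: m for m in filter_fixture}
        assert by_id["L2"].features.minor_axis <= 10.0
        assert by_id["L3"].features.major_axis <= 3.0

    def test_order_preserved_and_non_rule_organs_untouched(self, filter_fixture):
        kept = filter_lesions(filter_fixture)
        ids = [m.annotation.lesion_id for m in kept]
        assert ids == sorted(ids, key=lambda i: int(i[1:]))
        assert all(
            m.annotation.organ not in (OrganLabel.LYMPH_NODE, OrganLabel.LUNG)
            or m.features.minor_axis > 10
            or m.annotation.organ is OrganLabel.LUNG
            for m in kept
        )

    def test_degenerate_zero_area_lesion_dropped(self, filter_fixture):
        from .conftest import make_lesion
        from mmrd_burden.geometry import measure_lesions

        bad = measure_lesions(
            [make_lesion("Z1", OrganLabel.LIVER, Polygon2D([(0, 0), (1, 1), (2, 2)]))]
        )
        assert filter_lesions(list(filter_fixture) + bad) == filter_lesions(filter_fixture)
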