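"""Geometric measurement operations: centres, ray distances, offset index."""

import math

import numpy as np
import pytest
from shapely.geometry import LineString, Point, Polygon

from crvtoffset import (
    EyeDelineation,
    GeometryError,
    angular_deviation,
    bmo_center_and_area,
    boundary_distance,
    measure_crvt,
    ppa_areas,
    rnfl_defect_angle,
    synthesize_eye_geometry,
)
from crvtoffset.geometry import (
    _circular_midpoint_and_width,
    nasal_to_temporal_deg,
    wrap_angle_deg,
)
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_convex_polygon, regular_polygon


def ellipse_polygon(a, b, n=48, center=(0.0, 0.0), rotation=0.0):
    theta = 2.0 * math.pi * np.arange(n) / n
    pts = np.column_stack((a * np.cos(theta), b * np.sin(theta)))
    c, s = math.cos(rotation), math.sin(rotation)
    pts = pts @ np.array([[c, s], [-s, c]])
    return pts + np.asarray(center)


def brute_force_ray_distance(center, direction_deg, margin):
    """Independent oracle: clip a very long ray against the boundary with shapely."""
    theta = math.radians(direction_deg)
    span = 1e4 * float(np.abs(margin).max() + 1.0)
    ray = LineString(
        [center, (center[0] + span * math.cos(theta), center[1] + span * math.sin(theta))]
    )
    hit = ray.intersection(Polygon(margin).exterior)
    if hit.is_empty:
        raise AssertionError("oracle ray misses boundary")
    pts = [hit] if isinstance(hit, Point) else list(getattr(hit, "geoms", [hit]))
    return min(Point(center).distance(p) for p in pts)


class TestBmoCenterAndArea:
    def test_unit_square_with_extra_vertices(self):
        # midpoints added so the polygon has >= 8 vertices
        square = np.array(
            [(0, 0), (0.5, 0), (1, 0), (1, 0.5), (1, 1), (0.5, 1), (0, 1), (0, 0.5)],
            dtype=float,
        )
        (cx, cy), area = bmo_center_and_area(square)
        assert (cx, cy) == pytest.approx((0.5, 0.5), abs=1e-12)
        assert area == pytest.approx(1.0, abs=1e-12)

    def test_ellipse_area_matches_analytic(self):
        pts = ellipse_polygon(0.94, 0.90, n=48)
        _, area = bmo_center_and_area(pts)
        assert area == pytest.approx(math.pi * 0.94 * 0.90, rel=5e-3)

    def test_translation_equivariance(self, rng):
        pts = random_convex_polygon(rng)
        (cx, cy), area = bmo_center_and_area(pts)
        (cx2, cy2), area2 = bmo_center_and_area(pts + np.array([3.25, -1.5]))
        assert (cx2, cy2) == pytest.approx((cx + 3.25, cy - 1.5), abs=1e-12)
        assert area2 == pytest.approx(area, abs=1e-12)

    def test_vertex_order_invariance(self, rng):
        pts = random_convex_polygon(rng)
        center, area = bmo_center_and_area(pts)
        for variant in (pts[::-1], np.roll(pts, 11, axis=0)):
            c2, a2 = bmo_center_and_area(variant)
            assert c2 == pytest.approx(center, abs=1e-12)
            assert a2 == pytest.approx(area, abs=1e-12)

    @pytest.mark.parametrize(
        "bad",
        [
            # bowtie (self-intersecting)
            [(0, 0), (2, 2), (2, 0), (0, 2), (0.1, 1.9), (0.05, 1.0), (0.02, 0.5), (0.01, 0.2)],
            # collinear, zero area
            [(i, 0.0) for i in range(8)],
        ],
    )
    def test_degenerate_polygons_rejected(self, bad):
        with pytest.raises(GeometryError):
            bmo_center_and_area(np.array(bad, dtype=float))


class TestBoundaryDistance:
    def test_circle_radius(self):
        circle = regular_polygon(n=720)
        for direction in (0.0, 37.0, 90.0, -120.0, 180.0):
            assert boundary_distance((0, 0), direction, circle) == pytest.approx(
                1.0, abs=1e-3
            )

    def test_ellipse_axes(self):
        pts = ellipse_polygon(2.0, 1.0, n=4000)
        assert boundary_distance((0, 0), 0.0, pts) == pytest.approx(2.0, abs=1e-5)
        assert boundary_distance((0, 0), 90.0, pts) == pytest.approx(1.0, abs=1e-5)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            pts = random_convex_polygon(rng)
            (cx, cy), _ = bmo_center_and_area(pts)
            direction = rng.uniform(-180.0, 180.0)
            got = boundary_distance((cx, cy), direction, pts)
            want = brute_force_ray_distance((cx, cy), direction, pts)
            assert got == pytest.approx(want, abs=1e-9)

    def test_vertex_grazing_ray(self):
        # ray at 0 degrees from the centre of a regular polygon with a
        # vertex exactly on the +x axis: both adjacent segments are hit at
        # the same parameter
        pts = regular_polygon(n=8, radius=2.0)
        assert boundary_distance((0, 0), 0.0, pts) == pytest.approx(2.0, abs=1e-12)

    def test_center_outside_rejected(self):
        pts = regular_polygon(n=48)
        with pytest.raises(GeometryError):
            boundary_distance((5.0, 0.0), 0.0, pts)
        with pytest.raises(GeometryError):
            boundary_distance((1.0, 0.0), 0.0, pts)  # on the boundary


class TestMeasureCrvt:
    def make_eye(self, crvt, laterality="OD", outside=False, margin=None):
        return EyeDelineation(
            patient_id="p",
            laterality=laterality,
            margin_points=regular_polygon(n=96) if margin is None else margin,
            crvt_point=None if outside else crvt,
            crvt_outside_bmo=outside,
        )

    def test_crvt_at_centroid(self):
        m = measure_crvt(self.make_eye((0.0, 0.0)))
        assert m.offset_index == 0.0
        assert math.isnan(m.angular_deviation_deg)
        assert "crvt_at_center" in m.flags

    def test_outside_bmo_is_exactly_one(self):
        m = measure_crvt(self.make_eye(None, outside=True))
        assert m.offset_index == 1.0
        assert not m.angle_defined

    def test_halfway_along_nasal_axis(self):
        m = measure_crvt(self.make_eye((0.5, 0.0)))
        assert m.offset_index == pytest.approx(0.5, abs=1e-6)
        assert m.angular_deviation_deg == pytest.approx(0.0, abs=1e-9)

    def test_offset_index_clipped_to_unit_interval(self):
        # place the trunk essentially on the margin of a coarse polygon:
        # discretisation cannot push the ratio above 1
        margin = regular_polygon(n=8, radius=1.0)
        crvt = (0.999 * math.cos(0.3), 0.999 * math.sin(0.3))
        m = measure_crvt(self.make_eye(crvt, margin=margin))
        assert 0.0 <= m.offset_index <= 1.0

    def test_similarity_invariance(self, rng):
        for _ in range(20):
            idx = rng.uniform(0.05, 0.95)
            ang = rng.uniform(-179.0, 179.0)
            eye = synthesize_eye_geometry(idx, ang, "OD", 2.5, seed=int(rng.integers(2**31)))
            scale = rng.uniform(0.5, 2.0)
            rot = rng.uniform(0, 2 * math.pi)
            shift = rng.normal(scale=3.0, size=2)
            R = np.array(
                [[math.cos(rot), -math.sin(rot)], [math.sin(rot), math.cos(rot)]]
            )
            margin = (eye.margin_points * scale) @ R.T + shift
            crvt = tuple((np.array(eye.crvt_point) * scale) @ R.T + shift)
            moved = EyeDelineation("p", "OD", margin, crvt)
            m0, m1 = measure_crvt(eye), measure_crvt(moved)
            assert m1.offset_index == pytest.approx(m0.offset_index, abs=1e-9)
            # rotating the delineation co-rotates the reference axes
            assert wrap_angle_deg(
                m1.angular_deviation_deg - math.degrees(rot)
            ) == pytest.approx(m0.angular_deviation_deg, abs=1e-6)

    def test_os_equals_mirrored_od(self, rng):
        for _ in range(10):
            idx = rng.uniform(0.05, 0.95)
            ang = rng.uniform(-179.0, 179.0)
            seed = int(rng.integers(2**31))
            od = synthesize_eye_geometry(idx, ang, "OD", 2.5, seed=seed)
            mirrored = EyeDelineation(
                "p",
                "OS",
                od.margin_points * np.array([-1.0, 1.0]),
                (-od.crvt_point[0], od.crvt_point[1]),
            )
            m_od, m_os = measure_crvt(od), measure_crvt(mirrored)
            assert m_os.offset_index == pytest.approx(m_od.offset_index, abs=1e-12)
            assert m_os.angular_deviation_deg == pytest.approx(
                m_od.angular_deviation_deg, abs=1e-9
            )


class TestAngularDeviation:
    def test_cardinal_directions_od(self):
        assert angular_deviation((0, 0), (1, 0), "OD") == pytest.approx(0.0)
        assert angular_deviation((0, 0), (0, 1), "OD") == pytest.approx(90.0)
        assert angular_deviation((0, 0), (0, -1), "OD") == pytest.approx(-90.0)
        assert angular_deviation((0, 0), (-1, 0), "OD") == pytest.approx(180.0)

    def test_os_mirrors_to_od(self):
        # OS trunk displaced nasally in native coordinates (-x) maps to 0
        assert angular_deviation((0, 0), (-1, 0), "OS") == pytest.approx(0.0)
        assert angular_deviation((0, 0), (-1, 1), "OS") == pytest.approx(
            angular_deviation((0, 0), (1, 1), "OD")
        )

    def test_coincident_point_undefined(self):
        assert math.isnan(angular_deviation((1, 1), (1, 1), "OD"))


class TestRnflDefectAngle:
    def test_simple_midpoint(self):
        m = rnfl_defect_angle([(30.0, 60.0)])
        assert m.midpoint_angle_deg == pytest.approx(45.0)
        assert m.angular_width_deg == pytest.approx(30.0)

    def test_widest_defect_wins(self):
        m = rnfl_defect_angle([(-20.0, -60.0), (10.0, 30.0)])
        assert m.midpoint_angle_deg == pytest.approx(-40.0)
        assert m.angular_width_deg == pytest.approx(40.0)

    def test_inferior_sign_convention(self):
        m = rnfl_defect_angle([(-20.0, -60.0)])
        assert m.midpoint_angle_deg == pytest.approx(-40.0)

    def test_midpoint_crosses_wraparound(self):
        m = rnfl_defect_angle([(170.0, -170.0)])
        assert m.midpoint_angle_deg == pytest.approx(180.0)
        assert m.angular_width_deg == pytest.approx(20.0)

    def test_empty_list_gives_none(self):
        assert rnfl_defect_angle([]) is None

    def test_nasal_temporal_conversion(self):
        assert nasal_to_temporal_deg(0.0) == pytest.approx(180.0)
        assert nasal_to_temporal_deg(90.0) == pytest.approx(90.0)
        assert nasal_to_temporal_deg(-90.0) == pytest.approx(-90.0)


class TestAngleProperties:
    @given(st.floats(min_value=-5_000.0, max_value=5_000.0))
    @settings(derandomize=True, max_examples=200)
    def test_wrap_is_idempotent_and_in_range(self, angle):
        w = wrap_angle_deg(angle)
        assert -180.0 < w <= 180.0
        assert wrap_angle_deg(w) == pytest.approx(w, abs=1e-9)
        # wrapping preserves the direction
        assert math.cos(math.radians(w)) == pytest.approx(
            math.cos(math.radians(angle)), abs=1e-9
        )
        assert math.sin(math.radians(w)) == pytest.approx(
            math.sin(math.radians(angle)), abs=1e-9
        )

    @given(
        st.floats(min_value=-180.0, max_value=180.0),
        st.floats(min_value=1.0, max_value=179.0),
    )
    @settings(derandomize=True, max_examples=200)
    def test_circular_midpoint_bisects_the_arc(self, start, width):
        end = start + width  # may exceed 180; wrapping is the midpoint's job
        mid, got_width = _circular_midpoint_and_width(start, wrap_angle_deg(end))
        assert got_width == pytest.approx(width, abs=1e-9)
        # midpoint is equidistant (on the circle) from both boundaries
        d1 = abs(wrap_angle_deg(mid - start))
        d2 = abs(wrap_angle_deg(wrap_angle_deg(end) - mid))
        assert d1 == pytest.approx(d2, abs=1e-9)


class TestPpaAreas:
    def test_arithmetic(self):
        m = ppa_areas(2.0, 1.5, 1.8)
        assert m.beta_zone_area == pytest.approx(0.5)
        assert m.gamma_zone_area == pytest.approx(0.3)
        assert m.flags == ()

    def test_equal_areas_give_zero_beta(self):
        assert ppa_areas(1.5, 1.5, 1.8).beta_zone_area == 0.0

    def test_negative_result_flagged_but_returned(self):
        with pytest.warns(UserWarning, match="negative_beta_zone"):
            m = ppa_areas(1.0, 1.2, 1.1)
        assert m.beta_zone_area == pytest.approx(-0.2)
        assert "negative_beta_zone" in m.flags


class TestDelineationValidation:
    def test_outside_flag_excludes_point(self):
        with pytest.raises(GeometryError):
            EyeDelineation("p", "OD", regular_polygon(), (0, 0), crvt_outside_bmo=True)

    def test_point_required_when_inside(self):
        with pytest.raises(GeometryError):
            EyeDelineation("p", "OD", regular_polygon())

    def test_too_few_points(self):
        with pytest.raises(GeometryError):
            EyeDelineation("p", "OD", regular_polygon(n=6), (0, 0))
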