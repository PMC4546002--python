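"""Closed-form cornering geometry: tangent point, waypoints, angular rates."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from curvegaze.geometry import (
    BendGeometry,
    GeometryError,
    OutOfBendError,
    UndefinedTangentPointError,
    gaze_angle_rate,
    tangent_point_direction,
    vehicle_state_at,
    vertical_direction,
    waypoint_at_arc,
    waypoint_direction,
)

ARC90 = BendGeometry(inner_edge_radius=44.0, lane_width=8.0, arc_span=90.0)


class TestVehicleState:
    def test_onset_is_arc_position_zero(self):
        st0 = vehicle_state_at(ARC90, 48.0, 11.67, 0.0)
        assert st0.arc_position == 0.0

    def test_yaw_rate_magnitude_speed_over_radius(self):
        st0 = vehicle_state_at(ARC90, 48.0, 11.67, 0.0)
        assert abs(st0.yaw_rate) == pytest.approx(
            (11.67 / 48.0) * 180.0 / math.pi, abs=1e-9
        )
        assert abs(st0.yaw_rate) == pytest.approx(13.93, abs=5e-3)

    def test_quarter_circle_rotates_heading_90deg(self):
        speed, R = 11.67, 48.0
        t_quarter = (math.pi / 2 * R) / speed
        h0 = vehicle_state_at(ARC90, R, speed, 0.0).heading
        h1 = vehicle_state_at(ARC90, R, speed, t_quarter).heading
        turned = (h0 - h1) % 360.0  # right bend: heading rotates clockwise
        assert turned == pytest.approx(90.0, abs=1e-9)

    def test_position_stays_on_path_circle(self):
        for t in np.linspace(0.0, 6.0, 13):
            s = vehicle_state_at(ARC90, 48.0, 11.67, float(t))
            d = math.hypot(s.position[0] - ARC90.center[0],
                           s.position[1] - ARC90.center[1])
            assert d == pytest.approx(48.0, abs=1e-9)

    def test_beyond_arc_raises(self):
        with pytest.raises(OutOfBendError):
            vehicle_state_at(ARC90, 48.0, 11.67, 1e4)

    def test_radius_inside_inner_edge_raises(self):
        with pytest.raises(GeometryError):
            vehicle_state_at(ARC90, ARC90.inner_edge_radius, 11.67, 0.0)


class TestTangentPoint:
    def test_printed_value_at_50m_from_center(self):
        bend = BendGeometry(inner_edge_radius=48.0, lane_width=4.0)
        state = vehicle_state_at(bend, 50.0, 11.67, 1.0)
        d = tangent_point_direction(state, bend)
        assert abs(d.horizontal) == pytest.approx(
            90.0 - math.degrees(math.asin(48.0 / 50.0)), abs=1e-9
        )
        assert abs(d.horizontal) == pytest.approx(16.26, abs=5e-3)

    def test_constant_over_concentric_traversal(self, bend):
        R = bend.centerline_radius
        T = math.radians(bend.arc_span) * R / 11.67  # full traversal ≈ 9.7 s
        vals = [
            tangent_point_direction(vehicle_state_at(bend, R, 11.67, t), bend).horizontal
            for t in np.linspace(0.0, 0.99 * T, 101)
        ]
        assert max(vals) - min(vals) < 1e-9

    def test_undefined_inside_inner_circle(self):
        from curvegaze.geometry import VehicleState, tangent_point

        state = VehicleState((0.0, 10.0), 90.0, 10.0, 10.0, 48.0, 0.0)
        with pytest.raises(UndefinedTangentPointError):
            tangent_point(state, BendGeometry(center=(0.0, 0.0)))

    @pytest.mark.parametrize("handedness,sign", [("right", 1), ("left", -1)])
    def test_sign_toward_bend(self, handedness, sign):
        b = BendGeometry(bend_handedness=handedness)
        s = vehicle_state_at(b, b.centerline_radius, 11.67, 2.0)
        assert sign * tangent_point_direction(s, b).horizontal > 0


class TestWaypointDirection:
    def test_quarter_arc_endpoint_is_45deg(self):
        s0 = vehicle_state_at(ARC90, 48.0, 11.67, 0.0)
        end = waypoint_at_arc(s0, ARC90, 48.0 * math.pi / 2)
        assert abs(waypoint_direction(s0, end).horizontal) == pytest.approx(
            45.0, abs=1e-9
        )

    def test_sixty_degree_arc_gives_30(self):
        s0 = vehicle_state_at(ARC90, 48.0, 11.67, 0.0)
        w = waypoint_at_arc(s0, ARC90, 48.0 * math.radians(60.0))
        assert abs(waypoint_direction(s0, w).horizontal) == pytest.approx(
            30.0, abs=1e-9
        )

    def test_waypoint_at_vehicle_degenerates_to_zero(self):
        s0 = vehicle_state_at(ARC90, 48.0, 11.67, 0.0)
        assert waypoint_direction(s0, s0.position).horizontal == 0.0

    def test_behind_vehicle_raises(self):
        s0 = vehicle_state_at(ARC90, 48.0, 11.67, 1.0)
        behind = (
            s0.position[0] - 10.0 * s0.heading_vector[0],
            s0.position[1] - 10.0 * s0.heading_vector[1],
        )
        with pytest.raises(GeometryError):
            waypoint_direction(s0, behind)

    @given(
        arc=st.floats(1.0, 170.0),
        radius=st.floats(20.0, 120.0),
        t_frac=st.floats(0.0, 0.9),
    )
    def test_inscribed_angle_equals_half_remaining_arc(self, arc, radius, t_frac):
        """atan2 construction agrees with the ½-arc inscribed-angle formula."""
        bend = BendGeometry(
            inner_edge_radius=radius * 0.8, lane_width=radius * 0.4, arc_span=179.0
        )
        speed = 10.0
        t = t_frac * (math.radians(179.0 - arc) * radius) / speed
        s = vehicle_state_at(bend, radius, speed, t)
        w = waypoint_at_arc(s, bend, radius * math.radians(arc))
        assert abs(waypoint_direction(s, w).horizontal) == pytest.approx(
            arc / 2.0, abs=1e-8
        )


class TestGazeAngleRate:
    @pytest.mark.parametrize("radius", [30.0, 48.0, 90.0])
    @pytest.mark.parametrize("speed", [8.0, 11.67, 16.0])
    def test_half_rate_law_on_path(self, radius, speed):
        bend = BendGeometry(inner_edge_radius=radius - 5.0, lane_width=10.0)
        for arc_frac in (0.1, 0.4, 0.8):
            s = vehicle_state_at(bend, radius, speed, 0.0)
            w = waypoint_at_arc(s, bend, radius * math.radians(135.0) * arc_frac)
            rate = gaze_angle_rate(s, w)
            assert rate == pytest.approx(-0.5 * s.yaw_rate, abs=1e-9)
            assert abs(s.yaw_rate) / abs(rate) == pytest.approx(2.0, abs=1e-9)

    def test_matches_finite_difference_for_off_path_point(self):
        bend = BendGeometry()
        point = (30.0, 75.0)  # arbitrary world point, not on the path circle
        dt = 1e-3
        for t in (1.0, 3.0, 5.0):
            s = vehicle_state_at(bend, 49.0, 11.67, t)
            sm = vehicle_state_at(bend, 49.0, 11.67, t - dt / 2)
            sp = vehicle_state_at(bend, 49.0, 11.67, t + dt / 2)
            from curvegaze.geometry import egocentric_direction

            fd = (
                egocentric_direction(sp, point).horizontal
                - egocentric_direction(sm, point).horizontal
            ) / dt
            assert gaze_angle_rate(s, point) == pytest.approx(fd, abs=1e-5)

    def test_straight_driving_point_on_heading_is_static(self):
        from curvegaze.geometry import VehicleState

        s = VehicleState((0.0, 0.0), 90.0, 10.0, 0.0, 1e9, 0.0)
        assert gaze_angle_rate(s, (0.0, 100.0)) == pytest.approx(0.0, abs=1e-12)

    def test_sign_coherence_right_bend(self, bend):
        """Right bend: TP to the right (+), on-path flow leftward (−)."""
        s = vehicle_state_at(bend, bend.centerline_radius, 11.67, 1.0)
        w = waypoint_at_arc(s, bend, 25.0)
        assert tangent_point_direction(s, bend).horizontal > 0
        assert gaze_angle_rate(s, w) < 0


class TestVerticalDirection:
    def test_printed_value(self):
        from curvegaze.geometry import VehicleState

        s = VehicleState((0.0, 0.0), 90.0, 10.0, 0.0, 1e9, 0.0)
        assert vertical_direction(s, (0.0, 12.0), eye_height=1.2) == pytest.approx(
            math.degrees(math.atan(0.1)), abs=1e-9
        )
        assert vertical_direction(s, (0.0, 12.0), eye_height=1.2) == pytest.approx(
            5.71, abs=5e-3
        )

    def test_horizon_limit_and_monotone_approach(self):
        from curvegaze.geometry import VehicleState

        s = VehicleState((0.0, 0.0), 90.0, 10.0, 0.0, 1e9, 0.0)
        assert vertical_direction(s, (0.0, 1e9)) < 1e-6
        vals = [
            vertical_direction(
                VehicleState((0.0, float(y)), 90.0, 10.0, 0.0, 1e9, 0.0),
                (0.0, 100.0),
            )
            for y in range(0, 90, 10)
        ]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_zero_distance_raises(self):
        from curvegaze.geometry import VehicleState

        s = VehicleState((0.0, 0.0), 90.0, 10.0, 0.0, 1e9, 0.0)
        with pytest.raises(GeometryError):
            vertical_direction(s, (0.0, 0.0))
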