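"""Planar kinematics and egocentric visual geometry of constant-radius cornering.

A vehicle negotiating a constant-radius bend at constant speed moves on a
circle concentric with the lane edges.  Two classes of gaze target then
behave very differently in the driver's visual field:

* the **tangent point** (TP) — the point on the inside lane edge where the
  line of sight is tangential to the edge — keeps a *constant* egocentric
  direction (it travels with the observer);
* a **waypoint** — a world-fixed point on the future path — has an
  egocentric direction equal to half the remaining arc angle, and that
  direction closes at exactly half the vehicle's yaw rate.

Both facts are elementary circle geometry (the inscribed-angle theorem for
the waypoint case) and are exposed here in closed form so that simulated
gaze, detection and statistics can all be checked against ground truth.

Conventions
-----------
Allocentric frame: right-handed planar x/y in metres, angles measured
counter-clockwise from +x (internally in radians).  Egocentric horizontal
angles are in degrees, positive to the *right* of the instantaneous
heading; vertical angles are positive *below* the horizon.  Yaw rate is in
deg/s, positive for clockwise (rightward) rotation, so in a right-hand
bend the TP direction is positive and the gaze-line rotation rate of any
on-path waypoint is exactly ``-yaw_rate / 2`` for either handedness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Tuple

import numpy as np
from pydantic import BaseModel, model_validator

__all__ = [
    "GeometryError",
    "OutOfBendError",
    "UndefinedTangentPointError",
    "BendGeometry",
    "VehicleState",
    "EgocentricDirection",
    "vehicle_state_at",
    "tangent_point",
    "tangent_point_direction",
    "waypoint_direction",
    "waypoint_at_arc",
    "gaze_angle_rate",
    "vertical_direction",
    "egocentric_direction",
    "DEFAULT_EYE_HEIGHT",
]

#: Driver eye height above the road plane (m).  Not a measured quantity;
#: any positive value preserves every horizontal-geometry invariant.
DEFAULT_EYE_HEIGHT = 1.2


class GeometryError(ValueError):
    """Geometrically impossible configuration."""


class OutOfBendError(GeometryError):
    """Requested time/arc position lies beyond the bend."""


class UndefinedTangentPointError(GeometryError):
    """No tangent line exists (observer on or inside the inner edge circle)."""


class BendGeometry(BaseModel):
    """Parametric constant-radius bend.

    The inner lane edge is a circular arc of radius ``inner_edge_radius``
    about ``center``; the drivable centerline sits half a lane width
    further out.  ``entry_length`` metres of straight road precede the
    cornering onset and the final ``exit_cutoff`` metres of the arc are
    excluded from analysis (the driver *and* the gaze landing point must
    both be inside the constant-curvature section).
    """

    model_config = {"frozen": True}

    center: Tuple[float, float] = (0.0, 0.0)
    inner_edge_radius: float = 48.0
    lane_width: float = 3.5
    arc_span: float = 135.0
    bend_handedness: Literal["right", "left"] = "right"
    entry_length: float = 50.0
    exit_cutoff: float = 35.0

    @model_validator(mode="after")
    def _check(self) -> "BendGeometry":
        if self.inner_edge_radius <= 0:
            raise ValueError("inner_edge_radius must be > 0")
        if not (0 < self.arc_span <= 360):
            raise ValueError("arc_span must be in (0, 360]")
        if self.lane_width < 0 or self.entry_length < 0 or self.exit_cutoff < 0:
            raise ValueError("lengths must be non-negative")
        if self.exit_cutoff >= self.cornering_arc_length:
            raise ValueError(
                "exit_cutoff must be shorter than the cornering arc "
                f"({self.exit_cutoff} >= {self.cornering_arc_length:.1f} m)"
            )
        return self

    @property
    def centerline_radius(self) -> float:
        """Radius of the lane centerline (m)."""
        return self.inner_edge_radius + self.lane_width / 2.0

    @property
    def cornering_arc_length(self) -> float:
        """Arc length of the cornering phase along the centerline (m)."""
        return self.centerline_radius * math.radians(self.arc_span)

    @property
    def turn_sign(self) -> int:
        """+1 if the polar angle increases along travel (left bend), else -1."""
        return -1 if self.bend_handedness == "right" else 1


@dataclass(frozen=True)
class VehicleState:
    """Instantaneous vehicle pose on (or approaching) the bend.

    ``yaw_rate`` is signed clockwise-positive: positive in a right-hand
    bend, negative in a left-hand one.  ``arc_position`` is metres
    travelled along the path since cornering onset.
    """

    position: Tuple[float, float]
    heading: float  # deg, allocentric CCW from +x
    speed: float  # m/s
    yaw_rate: float  # deg/s, clockwise positive
    path_radius: float  # m
    arc_position: float  # m from cornering onset

    @property
    def heading_vector(self) -> np.ndarray:
        h = math.radians(self.heading)
        return np.array([math.cos(h), math.sin(h)])


@dataclass(frozen=True)
class EgocentricDirection:
    """A gaze direction relative to instantaneous heading.

    horizontal: deg, positive rightward of heading, in (-180, 180].
    vertical: deg, positive below the horizon (0 for points at infinity).
    """

    horizontal: float
    vertical: float = 0.0


def _wrap_deg(a: float | np.ndarray):
    """Wrap angle(s) to (-180, 180]."""
    w = (np.asarray(a) + 180.0) % 360.0 - 180.0
    w = np.where(w == -180.0, 180.0, w)
    return float(w) if np.isscalar(a) or np.ndim(a) == 0 else w


def vehicle_state_at(
    bend: BendGeometry,
    path_radius: float,
    speed: float,
    t: float,
    start_angle: float = 180.0,
) -> VehicleState:
    """Vehicle state ``t`` seconds after cornering onset.

    The vehicle moves at constant ``speed`` on the circle of
    ``path_radius`` about the bend center, heading tangential, entering
    at polar angle ``start_angle`` (deg) and turning with the bend's
    handedness.  Raises :class:`OutOfBendError` once the bend's
    ``arc_span`` has been traversed.
    """
    if path_radius <= bend.inner_edge_radius:
        raise GeometryError(
            f"path_radius {path_radius} must exceed inner_edge_radius "
            f"{bend.inner_edge_radius}"
        )
    if speed <= 0:
        raise GeometryError("speed must be > 0")
    omega = speed / path_radius  # rad/s, unsigned
    total_time = math.radians(bend.arc_span) / omega
    if t < 0 or t > total_time + 1e-12:
        raise OutOfBendError(
            f"t={t:.3f} s outside bend traversal [0, {total_time:.3f}] s"
        )
    s = bend.turn_sign
    phi = math.radians(start_angle) + s * omega * t
    cx, cy = bend.center
    pos = (cx + path_radius * math.cos(phi), cy + path_radius * math.sin(phi))
    # heading is the travel direction: d(pos)/dt ∝ s * (-sin phi, cos phi)
    heading = math.degrees(math.atan2(s * math.cos(phi), -s * math.sin(phi)))
    yaw_rate = -s * math.degrees(omega)  # clockwise positive
    return VehicleState(
        position=pos,
        heading=heading,
        speed=speed,
        yaw_rate=yaw_rate,
        path_radius=path_radius,
        arc_position=speed * t,
    )


def egocentric_direction(
    state: VehicleState,
    point: Tuple[float, float],
    eye_height: float | None = None,
) -> EgocentricDirection:
    """Egocentric direction of an allocentric ground point.

    Horizontal is rightward-positive relative to heading; if
    ``eye_height`` is given the vertical (below-horizon) angle of the
    ground point is filled in as well.
    """
    dx = point[0] - state.position[0]
    dy = point[1] - state.position[1]
    dist = math.hypot(dx, dy)
    if dist == 0.0:
        return EgocentricDirection(0.0, 90.0 if eye_height else 0.0)
    bearing = math.degrees(math.atan2(dy, dx))
    horizontal = _wrap_deg(state.heading - bearing)
    vertical = 0.0
    if eye_height is not None:
        vertical = math.degrees(math.atan(eye_height / dist))
    return EgocentricDirection(float(horizontal), float(vertical))


def tangent_point(state: VehicleState, bend: BendGeometry) -> Tuple[float, float]:
    """Allocentric position of the forward tangent point on the inner edge.

    Of the two tangent lines from the eye to the inner-edge circle, the
    forward one (largest projection on the heading) is returned.  Raises
    :class:`UndefinedTangentPointError` if the observer is on or inside
    the circle.
    """
    cx, cy = bend.center
    px, py = state.position
    r = bend.inner_edge_radius
    d = math.hypot(px - cx, py - cy)
    if d <= r:
        raise UndefinedTangentPointError(
            f"observer distance {d:.2f} m <= inner edge radius {r:.2f} m"
        )
    gamma = math.atan2(py - cy, px - cx)  # bearing of observer from center
    theta = math.acos(r / d)  # half-angle subtended at the center
    candidates = []
    for sign in (+1, -1):
        ang = gamma + sign * theta
        tp = (cx + r * math.cos(ang), cy + r * math.sin(ang))
        ahead = (tp[0] - px) * state.heading_vector[0] + (
            tp[1] - py
        ) * state.heading_vector[1]
        candidates.append((ahead, tp))
    return max(candidates, key=lambda c: c[0])[1]


def tangent_point_direction(
    state: VehicleState,
    bend: BendGeometry,
    eye_height: float | None = DEFAULT_EYE_HEIGHT,
) -> EgocentricDirection:
    """Egocentric direction of the tangent point.

    For a vehicle on a circle concentric with the lane edge the
    horizontal magnitude is ``90° − arcsin(r/d)`` with ``r`` the inner
    edge radius and ``d`` the distance from the bend center — constant
    in time, signed toward the bend.
    """
    return egocentric_direction(state, tangent_point(state, bend), eye_height)


def waypoint_at_arc(
    state: VehicleState, bend: BendGeometry, arc_ahead: float
) -> Tuple[float, float]:
    """World point on the vehicle's path circle ``arc_ahead`` metres ahead."""
    if arc_ahead < 0:
        raise GeometryError("arc_ahead must be >= 0")
    cx, cy = bend.center
    px, py = state.position
    phi = math.atan2(py - cy, px - cx)
    s = bend.turn_sign
    phi2 = phi + s * arc_ahead / state.path_radius
    return (
        cx + state.path_radius * math.cos(phi2),
        cy + state.path_radius * math.sin(phi2),
    )


def waypoint_direction(
    state: VehicleState,
    waypoint: Tuple[float, float],
    eye_height: float | None = DEFAULT_EYE_HEIGHT,
) -> EgocentricDirection:
    """Egocentric direction of a world-fixed waypoint ahead of the vehicle.

    For a waypoint on the vehicle's own path circle the inscribed-angle
    theorem gives a horizontal magnitude of half the remaining arc angle
    (e.g. 45° for the far end of a 90° arc).  Computed here directly from
    coordinates, so it is equally valid for off-path points.  Raises
    :class:`GeometryError` for points behind the vehicle.
    """
    dx = waypoint[0] - state.position[0]
    dy = waypoint[1] - state.position[1]
    if math.hypot(dx, dy) < 1e-12:
        return EgocentricDirection(0.0, 0.0)
    direction = egocentric_direction(state, waypoint, eye_height)
    if abs(direction.horizontal) > 90.0 + 1e-9:
        raise GeometryError("waypoint lies behind the vehicle")
    return direction


def gaze_angle_rate(state: VehicleState, fixed_point: Tuple[float, float]) -> float:
    """Rotation rate (deg/s) of the line of sight to a world-fixed point.

    Rightward-positive, i.e. the time derivative of the egocentric
    horizontal direction.  For any fixed point on the vehicle's path
    circle this equals ``-yaw_rate / 2``: the eye counter-rotates at
    exactly half the vehicle's rotation rate, whatever the remaining arc.
    """
    ux = fixed_point[0] - state.position[0]
    uy = fixed_point[1] - state.position[1]
    d2 = ux * ux + uy * uy
    if d2 == 0.0:
        raise GeometryError("fixed point coincides with the observer")
    h = math.radians(state.heading)
    vx = state.speed * math.cos(h)
    vy = state.speed * math.sin(h)
    bearing_rate = (vx * uy - vy * ux) / d2  # rad/s, CCW positive
    heading_rate = -math.radians(state.yaw_rate)  # CCW positive
    return math.degrees(heading_rate - bearing_rate)


def vertical_direction(
    state: VehicleState,
    ground_point: Tuple[float, float],
    eye_height: float = DEFAULT_EYE_HEIGHT,
) -> float:
    """Below-horizon angle (deg) of a ground-plane point.

    ``arctan(eye_height / ground_distance)``; grows monotonically as the
    point is approached.
    """
    if eye_height <= 0:
        raise GeometryError("eye_height must be > 0")
    dist = math.hypot(
        ground_point[0] - state.position[0], ground_point[1] - state.position[1]
    )
    if dist == 0.0:
        raise GeometryError("ground distance is zero")
    return math.degrees(math.atan(eye_height / dist))
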