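"""Seeded simulator of curve-driving gaze trials.

Emulates the sensor suite of an instrumented-car eye-tracking study:
60 Hz remote gaze tracking (horizontal/vertical angle + a 0–1 quality
signal), 100 Hz CAN-bus speed and yaw rate, and 1 Hz GPS position, for a
vehicle driving a straight approach, a 50 m entry and a constant-radius
bend (radius ≈ 48 m at ≈ 42 km/h).

Three gaze strategies are generated, matching the competing steering
models under test:

``waypoint``
    Optokinetic nystagmus from sequential fixation of world-fixed points
    on the future path: 200–400 ms slow phases tracking a waypoint placed
    a preview time ahead, interleaved with short resetting saccades.
    During each slow phase the noiseless horizontal gaze velocity is
    exactly −½ × yaw rate.
``tp``
    Perfect tangent-point fixation: the gaze trace is constant during
    cornering (the TP keeps a fixed egocentric direction).
``tp_okr``
    TP fixation contaminated by an unsuppressed optokinetic reflex: gaze
    drifts with a gain on the local optic flow at the TP and is reset by
    small corrective saccades.

Every trial carries a ground-truth event log (slow phases and saccades
with exact sample times), so detection and statistics are testable
without any external data.  All randomness flows from explicit seeds via
``numpy.random.default_rng``; a fixed seed reproduces a trial exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .geometry import (
    DEFAULT_EYE_HEIGHT,
    BendGeometry,
    GeometryError,
)

__all__ = [
    "StrategyParams",
    "SimConfig",
    "GroundTruthEvent",
    "TrialRecord",
    "Route",
    "simulate_trial",
    "add_sensor_noise",
    "simulate_cohort",
    "GAZE_RATE_HZ",
    "CAN_RATE_HZ",
    "GPS_RATE_HZ",
]

GAZE_RATE_HZ = 60.0
CAN_RATE_HZ = 100.0
GPS_RATE_HZ = 1.0

#: quality value below which the tracker is considered to have lost the eye
QUALITY_THRESHOLD = 0.2


class StrategyParams(BaseModel):
    """Parameters of one simulated driver's gaze strategy and sensor noise.

    ``noise_sd`` is white tracker noise per axis (deg); ``vibration_ar1``
    and ``vibration_sd`` define an AR(1) low-frequency wander emulating
    shake of the dashboard-mounted tracker; ``dropout_prob`` is the
    per-sample probability of a quality dropout.  ``okr_gain`` scales the
    reflexive drift in the ``tp_okr`` strategy.
    """

    model_config = {"frozen": True}

    strategy: Literal["waypoint", "tp", "tp_okr"] = "waypoint"
    preview_time: float = 2.0  # s of look-ahead for waypoint placement
    sp_duration_range: Tuple[float, float] = (0.2, 0.4)  # s
    saccade_peak_speed: float = 300.0  # deg/s
    noise_sd: float = 0.35  # deg, white
    vibration_ar1: float = 0.95
    vibration_sd: float = 0.1  # deg, AR(1) innovation
    dropout_prob: float = 0.02
    okr_gain: float = 0.5
    eye_height: float = DEFAULT_EYE_HEIGHT

    @model_validator(mode="after")
    def _check(self) -> "StrategyParams":
        lo, hi = self.sp_duration_range
        if not (0 < lo < hi):
            raise ValueError("sp_duration_range must satisfy 0 < low < high")
        if not (0 <= self.dropout_prob <= 1):
            raise ValueError("dropout_prob must be in [0, 1]")
        if not (0 <= self.okr_gain <= 1):
            raise ValueError("okr_gain must be in [0, 1]")
        if self.preview_time <= 0 or self.saccade_peak_speed <= 0:
            raise ValueError("preview_time and saccade_peak_speed must be > 0")
        if not (0 <= self.vibration_ar1 < 1):
            raise ValueError("vibration_ar1 must be in [0, 1)")
        return self


class SimConfig(BaseModel):
    """Cohort-level simulation design.

    Defaults reproduce the experiment's design: 7 subjects driving 8
    trials per condition in alternating blocks normal–tp–normal–tp, at
    a mean speed of 42 km/h (11.67 m/s, between-subject SD 1.1 m/s) on a
    48 m bend.
    """

    model_config = {"frozen": True}

    n_subjects: int = 7
    trials_per_condition: int = 8
    bends: Tuple[BendGeometry, ...] = (BendGeometry(),)
    speed_mean: float = 11.67  # m/s  (42 km/h)
    speed_sd: float = 1.1  # m/s  (≈ 3.95 km/h)
    params: StrategyParams = StrategyParams()
    preview_jitter_sd: float = 0.3  # s, between subjects
    radius_jitter_sd: float = 0.3  # m, per-trial lane-position jitter
    strategy_by_condition: Dict[str, str] = Field(
        default_factory=lambda: {"normal": "waypoint", "tp": "tp"}
    )
    master_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.n_subjects < 1 or self.trials_per_condition < 1:
            raise ValueError("counts must be >= 1")
        if self.speed_mean <= 0:
            raise ValueError("speed_mean must be > 0")
        if not self.bends:
            raise ValueError("at least one bend required")
        return self


@dataclass(frozen=True)
class GroundTruthEvent:
    """One generated oculomotor event (sample-exact)."""

    start_s: float
    end_s: float
    kind: str  # "slow_phase" | "saccade"
    target: str  # fixated target id


@dataclass
class TrialRecord:
    """One simulated cornering trial, multirate, with ground truth.

    ``gaze`` is the 60 Hz tracker stream (t, gh_deg, gv_deg, quality,
    plus the geometric ground-truth TP direction tp_h_deg/tp_v_deg);
    ``vehicle`` the 100 Hz CAN stream (t, speed_mps, yaw_dps); ``gps``
    the 1 Hz position stream (t, x_m, y_m).
    """

    gaze: pd.DataFrame
    vehicle: pd.DataFrame
    gps: pd.DataFrame
    subject: int
    trial: int
    condition: str
    bend_id: int
    ground_truth: List[GroundTruthEvent]
    meta: Dict = field(default_factory=dict)

    @property
    def bend(self) -> BendGeometry:
        return BendGeometry(**self.meta["bend"])

    def copy(self) -> "TrialRecord":
        return TrialRecord(
            gaze=self.gaze.copy(),
            vehicle=self.vehicle.copy(),
            gps=self.gps.copy(),
            subject=self.subject,
            trial=self.trial,
            condition=self.condition,
            bend_id=self.bend_id,
            ground_truth=list(self.ground_truth),
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        """Merge the three streams onto the 60 Hz gaze timebase.

        CAN signals are taken as the nearest preceding 100 Hz sample,
        GPS is linearly interpolated — the same rules the preprocessing
        stage applies.
        """
        t = self.gaze["t"].to_numpy()
        tv = self.vehicle["t"].to_numpy()
        idx = np.clip(np.searchsorted(tv, t, side="right") - 1, 0, len(tv) - 1)
        tg = self.gps["t"].to_numpy()
        out = self.gaze.copy()
        out["speed_mps"] = self.vehicle["speed_mps"].to_numpy()[idx]
        out["yaw_dps"] = self.vehicle["yaw_dps"].to_numpy()[idx]
        out["x_m"] = np.interp(t, tg, self.gps["x_m"].to_numpy())
        out["y_m"] = np.interp(t, tg, self.gps["y_m"].to_numpy())
        out["subject"] = self.subject
        out["trial"] = self.trial
        out["condition"] = self.condition
        cols = [
            "t", "gh_deg", "gv_deg", "quality", "speed_mps", "yaw_dps",
            "x_m", "y_m", "subject", "trial", "condition",
            "tp_h_deg", "tp_v_deg",
        ]
        return out[cols]


@dataclass(frozen=True)
class Route:
    """Straight approach + entry, constant-radius arc, straight exit.

    Distances are metres along the driven path from trial start; the
    cornering onset is at ``approach_length + bend.entry_length``.
    """

    bend: BendGeometry
    path_radius: float
    speed: float
    approach_length: float = 40.0
    exit_length: float = 15.0
    start_angle: float = 180.0  # deg, polar angle of cornering onset

    def __post_init__(self):
        if self.path_radius <= self.bend.inner_edge_radius:
            raise GeometryError("path_radius must exceed the inner edge radius")
        if self.speed <= 0:
            raise GeometryError("speed must be > 0")

    @property
    def onset_dist(self) -> float:
        return self.approach_length + self.bend.entry_length

    @property
    def arc_length(self) -> float:
        """Arc length of the vehicle's own path through the bend."""
        return self.path_radius * math.radians(self.bend.arc_span)

    @property
    def total_length(self) -> float:
        return self.onset_dist + self.arc_length + self.exit_length

    @property
    def total_time(self) -> float:
        return self.total_length / self.speed

    @property
    def t_onset(self) -> float:
        return self.onset_dist / self.speed

    @property
    def t_arc_end(self) -> float:
        return (self.onset_dist + self.arc_length) / self.speed

    def pose_at_dist(self, d: np.ndarray):
        """Vectorized pose: (x, y, heading_deg, yaw_dps) at distances ``d``."""
        d = np.asarray(d, dtype=float)
        b, R = self.bend, self.path_radius
        s = b.turn_sign
        cx, cy = b.center
        phi0 = math.radians(self.start_angle)
        x0 = cx + R * math.cos(phi0)
        y0 = cy + R * math.sin(phi0)
        psi0 = math.atan2(s * math.cos(phi0), -s * math.sin(phi0))
        h0 = np.array([math.cos(psi0), math.sin(psi0)])
        D0, arc = self.onset_dist, self.arc_length
        yaw_mag = math.degrees(self.speed / R)

        x = np.empty_like(d)
        y = np.empty_like(d)
        psi = np.empty_like(d)
        yaw = np.zeros_like(d)

        pre = d < D0
        x[pre] = x0 - h0[0] * (D0 - d[pre])
        y[pre] = y0 - h0[1] * (D0 - d[pre])
        psi[pre] = psi0

        on = (d >= D0) & (d <= D0 + arc)
        theta = (d[on] - D0) / R
        phi = phi0 + s * theta
        x[on] = cx + R * np.cos(phi)
        y[on] = cy + R * np.sin(phi)
        psi[on] = np.arctan2(s * np.cos(phi), -s * np.sin(phi))
        yaw[on] = -s * yaw_mag  # clockwise positive

        post = d > D0 + arc
        if post.any():
            phie = phi0 + s * math.radians(b.arc_span)
            xe = cx + R * math.cos(phie)
            ye = cy + R * math.sin(phie)
            psie = math.atan2(s * math.cos(phie), -s * math.sin(phie))
            x[post] = xe + math.cos(psie) * (d[post] - D0 - arc)
            y[post] = ye + math.sin(psie) * (d[post] - D0 - arc)
            psi[post] = psie
        return x, y, np.degrees(psi), yaw

    def pose_at_time(self, t: np.ndarray):
        return self.pose_at_dist(np.asarray(t, dtype=float) * self.speed)


def _wrap(a):
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


def _ego_dir(px, py, psi_deg, wx, wy, eye_height):
    """Vectorized egocentric direction of world point (wx, wy)."""
    dx = wx - px
    dy = wy - py
    dist = np.hypot(dx, dy)
    bearing = np.degrees(np.arctan2(dy, dx))
    h = _wrap(psi_deg - bearing)
    with np.errstate(divide="ignore"):
        v = np.degrees(np.arctan(eye_height / np.maximum(dist, 1e-9)))
    return h, v, dist


def _tp_dir(px, py, psi_deg, bend: BendGeometry, eye_height):
    """Vectorized egocentric direction of the forward tangent point."""
    cx, cy = bend.center
    r = bend.inner_edge_radius
    dx = px - cx
    dy = py - cy
    d = np.hypot(dx, dy)
    gamma = np.arctan2(dy, dx)
    theta = np.arccos(np.clip(r / np.maximum(d, r), -1.0, 1.0))
    psi = np.radians(psi_deg)
    hx, hy = np.cos(psi), np.sin(psi)
    best_h = np.full_like(d, np.nan)
    best_v = np.full_like(d, np.nan)
    best_ahead = np.full_like(d, -np.inf)
    for sign in (+1.0, -1.0):
        ang = gamma + sign * theta
        tx = cx + r * np.cos(ang)
        ty = cy + r * np.sin(ang)
        ahead = (tx - px) * hx + (ty - py) * hy
        h, v, _ = _ego_dir(px, py, psi_deg, tx, ty, eye_height)
        take = ahead > best_ahead
        best_h = np.where(take, h, best_h)
        best_v = np.where(take, v, best_v)
        best_ahead = np.maximum(best_ahead, ahead)
    return best_h, best_v


def _sp_sample_count(rng, params: StrategyParams, fs: float) -> int:
    lo, hi = params.sp_duration_range
    return int(round(rng.uniform(lo, hi) * fs))


def simulate_trial(
    bend: BendGeometry,
    params: StrategyParams,
    speed: float,
    seed,
    *,
    path_radius: Optional[float] = None,
    subject: int = 0,
    trial: int = 0,
    condition: Optional[str] = None,
    approach_length: float = 40.0,
    exit_length: float = 15.0,
) -> TrialRecord:
    """Simulate one clean (noiseless) trial.

    The returned record has exact gaze per the strategy; call
    :func:`add_sensor_noise` to superimpose tracker noise.  A fixed
    ``seed`` reproduces the trial exactly.  If the waypoint preview
    reaches beyond the bend exit the waypoint is clamped to the arc end
    and ``meta["truncated"]`` is set.
    """
    rng = np.random.default_rng(seed)
    if path_radius is None:
        path_radius = bend.centerline_radius
    route = Route(
        bend=bend,
        path_radius=path_radius,
        speed=speed,
        approach_length=approach_length,
        exit_length=exit_length,
    )
    fs = GAZE_RATE_HZ
    n60 = int(math.floor(route.total_time * fs)) + 1
    t60 = np.arange(n60) / fs
    px, py, psi, _yaw60 = route.pose_at_time(t60)

    # default gaze: look at the tangent point throughout
    gh, gv = _tp_dir(px, py, psi, bend, params.eye_height)
    tp_h, tp_v = gh.copy(), gv.copy()

    # cornering sample window [k_on, k_off)
    k_on = int(np.searchsorted(t60, route.t_onset, side="left"))
    k_off = int(np.searchsorted(t60, route.t_arc_end, side="right"))
    events: List[GroundTruthEvent] = []
    truncated = False

    if params.strategy == "tp":
        events.append(
            GroundTruthEvent(t60[k_on], t60[k_off - 1], "slow_phase", "tp")
        )
    elif params.strategy == "waypoint":
        k = k_on
        wp_idx = 0
        while k < k_off:
            sp_n = max(2, _sp_sample_count(rng, params, fs))
            end = min(k + sp_n, k_off)
            arc_ahead = params.preview_time * speed
            remaining = route.arc_length + route.onset_dist - t60[k] * speed
            if arc_ahead > remaining:
                arc_ahead = max(remaining, 1e-6)
                truncated = True
            # world-fixed waypoint on the path circle, preview ahead
            dist_w = t60[k] * speed + arc_ahead
            wx, wy, _, _ = route.pose_at_dist(np.array([dist_w]))
            wx, wy = float(wx[0]), float(wy[0])
            sl = slice(k, end)
            h, v, _ = _ego_dir(px[sl], py[sl], psi[sl], wx, wy, params.eye_height)
            gh[sl], gv[sl] = h, v
            events.append(
                GroundTruthEvent(
                    t60[k], t60[end - 1], "slow_phase", f"wp{wp_idx}"
                )
            )
            if end >= k_off:
                break
            # resetting saccade to the next waypoint
            wp_idx += 1
            dist_w2 = t60[end] * speed + min(
                params.preview_time * speed,
                max(route.arc_length + route.onset_dist - t60[end] * speed, 1e-6),
            )
            w2x, w2y, _, _ = route.pose_at_dist(np.array([dist_w2]))
            w2x, w2y = float(w2x[0]), float(w2y[0])
            g0 = np.array([gh[end - 1], gv[end - 1]])
            h1, v1, _ = _ego_dir(
                px[end], py[end], psi[end], w2x, w2y, params.eye_height
            )
            amp = float(np.hypot(h1 - g0[0], v1 - g0[1]))
            sac_n = int(np.clip(math.ceil(amp / params.saccade_peak_speed * fs), 2, 4))
            sac_n = min(sac_n, k_off - end)
            if sac_n < 1:
                break
            frac = np.arange(1, sac_n + 1) / sac_n
            gh[end : end + sac_n] = g0[0] + frac * (h1 - g0[0])
            gv[end : end + sac_n] = g0[1] + frac * (v1 - g0[1])
            events.append(
                GroundTruthEvent(
                    t60[end], t60[end + sac_n - 1], "saccade", f"wp{wp_idx}"
                )
            )
            k = end + sac_n
    elif params.strategy == "tp_okr":
        # TP fixation with reflexive drift along local optic flow
        k = k_on
        while k < k_off:
            sp_n = max(2, _sp_sample_count(rng, params, fs))
            end = min(k + sp_n, k_off)
            # world point currently under the TP; gaze drifts with its flow
            cxp, cyp = bend.center
            r = bend.inner_edge_radius
            gamma = math.atan2(py[k] - cyp, px[k] - cxp)
            theta = math.acos(min(r / math.hypot(px[k] - cxp, py[k] - cyp), 1.0))
            s = bend.turn_sign
            ang = gamma + s * theta  # forward tangent point
            wx = cxp + r * math.cos(ang)
            wy = cyp + r * math.sin(ang)
            h, v, _ = _ego_dir(px[k:end], py[k:end], psi[k:end], wx, wy,
                               params.eye_height)
            gh[k:end] = tp_h[k:end] + params.okr_gain * (h - h[0])
            gv[k:end] = tp_v[k:end] + params.okr_gain * (v - v[0])
            events.append(
                GroundTruthEvent(t60[k], t60[end - 1], "slow_phase", "tp_okr")
            )
            if end >= k_off:
                break
            sac_n = min(2, k_off - end)
            if sac_n < 1:
                break
            g0 = np.array([gh[end - 1], gv[end - 1]])
            frac = np.arange(1, sac_n + 1) / sac_n
            gh[end : end + sac_n] = g0[0] + frac * (tp_h[end + sac_n - 1] - g0[0])
            gv[end : end + sac_n] = g0[1] + frac * (tp_v[end + sac_n - 1] - g0[1])
            events.append(
                GroundTruthEvent(t60[end], t60[end + sac_n - 1], "saccade", "reset")
            )
            k = end + sac_n
    else:  # pragma: no cover - validated by StrategyParams
        raise ValueError(f"unknown strategy {params.strategy!r}")

    # after the arc: hold the last cornering gaze value (tracker keeps
    # reporting; the analysis never uses these samples)
    if k_off < n60:
        gh[k_off:] = gh[k_off - 1]
        gv[k_off:] = gv[k_off - 1]

    gaze = pd.DataFrame(
        {
            "t": t60,
            "gh_deg": gh,
            "gv_deg": gv,
            "quality": np.ones(n60),
            "tp_h_deg": tp_h,
            "tp_v_deg": tp_v,
        }
    )
    n100 = int(math.floor(route.total_time * CAN_RATE_HZ)) + 1
    t100 = np.arange(n100) / CAN_RATE_HZ
    _, _, _, yaw100 = route.pose_at_time(t100)
    vehicle = pd.DataFrame(
        {"t": t100, "speed_mps": np.full(n100, speed), "yaw_dps": yaw100}
    )
    t1 = np.arange(0.0, math.floor(route.total_time) + 1.0)
    gx, gy, _, _ = route.pose_at_time(t1)
    gps = pd.DataFrame({"t": t1, "x_m": gx, "y_m": gy})

    if condition is None:
        condition = "normal" if params.strategy == "waypoint" else "tp"
    meta = {
        "bend": bend.model_dump(),
        "path_radius": path_radius,
        "speed": speed,
        "onset_dist_m": route.onset_dist,
        "cornering_end_m": route.onset_dist + bend.cornering_arc_length,
        "approach_length_m": approach_length,
        "exit_length_m": exit_length,
        "strategy": params.strategy,
        "eye_height": params.eye_height,
        "truncated": truncated,
        "traffic": False,
        "weather": False,
    }
    return TrialRecord(
        gaze=gaze,
        vehicle=vehicle,
        gps=gps,
        subject=subject,
        trial=trial,
        condition=condition,
        bend_id=0,
        ground_truth=events,
        meta=meta,
    )


def add_sensor_noise(trial: TrialRecord, params: StrategyParams, seed) -> TrialRecord:
    """Superimpose tracker noise on a clean trial.

    Adds per-axis white Gaussian noise (``noise_sd``) plus an AR(1)
    vibration wander (coefficient ``vibration_ar1``, innovation
    ``vibration_sd``), and draws quality dropouts (``dropout_prob``)
    whose quality falls below the 0.2 criterion.  Ground truth is
    untouched.
    """
    rng = np.random.default_rng(seed)
    out = trial.copy()
    n = len(out.gaze)
    for col in ("gh_deg", "gv_deg"):
        white = rng.normal(0.0, params.noise_sd, n) if params.noise_sd > 0 else 0.0
        if params.vibration_sd > 0:
            c = params.vibration_ar1
            innov = rng.normal(0.0, params.vibration_sd, n)
            ar = np.empty(n)
            stat_sd = params.vibration_sd / math.sqrt(max(1.0 - c * c, 1e-12))
            ar[0] = rng.normal(0.0, stat_sd)
            for i in range(1, n):
                ar[i] = c * ar[i - 1] + innov[i]
        else:
            ar = 0.0
        out.gaze[col] = out.gaze[col].to_numpy() + white + ar
    if params.dropout_prob > 0:
        # blink-like dropout bursts (mean ~130 ms at 60 Hz); the
        # per-sample marginal probability equals dropout_prob
        mean_burst = 8.0
        # two-state Markov occupancy: stationary dropout fraction equals
        # dropout_prob when bursts start from good samples at this rate
        start_p = params.dropout_prob / (
            mean_burst * max(1.0 - params.dropout_prob, 1e-9)
        )
        drop = np.zeros(n, bool)
        i = 0
        while i < n:
            if rng.random() < start_p:
                burst = rng.geometric(1.0 / mean_burst)
                drop[i : i + burst] = True
                i += burst
            else:
                i += 1
        q = rng.uniform(0.25, 1.0, n)
        q[drop] = rng.uniform(0.0, QUALITY_THRESHOLD - 0.05, int(drop.sum()))
        out.gaze["quality"] = q
    return out


def condition_blocks(trials_per_condition: int) -> List[str]:
    """Block order normal–tp–normal–tp over 2×trials_per_condition runs."""
    a = (trials_per_condition + 1) // 2
    b = trials_per_condition - a
    return ["normal"] * a + ["tp"] * a + ["normal"] * b + ["tp"] * b


def simulate_cohort(config: SimConfig) -> List[TrialRecord]:
    """Simulate a full cohort under the blocked two-condition design.

    Subjects get jittered speeds and preview times; each trial gets a
    small lane-position (path radius) jitter.  Deterministic under
    ``config.master_seed``.
    """
    trials: List[TrialRecord] = []
    order = condition_blocks(config.trials_per_condition)
    base = config.params
    for subj in range(1, config.n_subjects + 1):
        s_rng = np.random.default_rng([config.master_seed, 1000 + subj])
        speed = float(
            np.clip(s_rng.normal(config.speed_mean, config.speed_sd), 6.0, 20.0)
        )
        preview = float(
            max(0.8, s_rng.normal(base.preview_time, config.preview_jitter_sd))
        )
        # individual differences in tracker quality and OKN timing
        noise_sd = float(base.noise_sd * s_rng.lognormal(0.0, 0.3))
        vibration_sd = float(base.vibration_sd * s_rng.lognormal(0.0, 0.3))
        dropout = float(np.clip(base.dropout_prob * s_rng.lognormal(0.0, 0.5), 0, 0.2))
        lo, hi = base.sp_duration_range
        shift = float(s_rng.normal(0.0, 0.03))
        sp_range = (max(0.1, lo + shift), hi + shift)
        for idx, condition in enumerate(order, start=1):
            bend = config.bends[(idx - 1) % len(config.bends)]
            t_rng = np.random.default_rng([config.master_seed, 1000 + subj, idx])
            radius = bend.centerline_radius + float(
                t_rng.normal(0.0, config.radius_jitter_sd)
            )
            radius = max(radius, bend.inner_edge_radius + 0.5)
            strategy = config.strategy_by_condition.get(condition, "waypoint")
            params = base.model_copy(
                update={
                    "strategy": strategy,
                    "preview_time": preview,
                    "noise_sd": noise_sd,
                    "vibration_sd": vibration_sd,
                    "dropout_prob": dropout,
                    "sp_duration_range": sp_range,
                }
            )
            clean = simulate_trial(
                bend,
                params,
                speed,
                [config.master_seed, 2000 + subj, idx],
                path_radius=radius,
                subject=subj,
                trial=idx,
                condition=condition,
            )
            clean.bend_id = (idx - 1) % len(config.bends)
            noisy = add_sensor_noise(
                clean, params, [config.master_seed, 3000 + subj, idx]
            )
            trials.append(noisy)
    return trials
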