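"""Optimal piecewise-linear segmentation of 2-D gaze traces.

Slow eye movements (smooth pursuit / optokinetic slow phases), fixations
and saccades all have approximately constant velocity on the time scale
of one event, so a gaze trace is well described as a sequence of linear
segments — with saccades showing much steeper slopes.  Simply
differentiating a vibration-contaminated tracker signal drowns the slow
phases in noise, and low-pass filtering destroys the very structure of
interest.  Instead the trace is *optimally partitioned* into linear
segments: the partition minimizing

    sum over segments of SSE(least-squares line, both axes) + penalty × k

(k = number of segments) is found exactly by dynamic programming over
candidate breakpoints.  Both gaze axes share breakpoints and their
residuals are summed, since the eye moves as one.

Segments are then classified: fewer than ``min_samples`` samples
(default 12, i.e. 200 ms at 60 Hz) → discarded; fitted speed at or above
``speed_threshold`` (default 50 deg/s) → saccade; otherwise slow phase.
Per-segment velocity is the least-squares slope; amplitude is the
difference of the fitted values at the segment's ends; speed is
amplitude norm over duration; direction is measured from vehicle-frame
vertical (0° = upward, positive clockwise, so "left and down" falls on
the negative side).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "PartitionSolution",
    "GazeSegment",
    "partition_signal",
    "select_penalty",
    "classify_segments",
    "segment_velocity",
    "split_on_gaps",
    "DEFAULT_MIN_SAMPLES",
    "DEFAULT_SACCADE_THRESHOLD",
    "DEFAULT_PENALTY_CONSTANT",
]

DEFAULT_MIN_SAMPLES = 12  # 200 ms at 60 Hz
DEFAULT_SACCADE_THRESHOLD = 50.0  # deg/s
DEFAULT_PENALTY_CONSTANT = 4.0
#: minimum segment length in samples inside the partitioner (a line
#: needs two points)
MIN_SEGMENT_SAMPLES = 2
#: floor on the robust noise estimate (deg), covering quantization of a
#: noiseless trace
SIGMA_FLOOR = 0.05


@dataclass(frozen=True)
class PartitionSolution:
    """Exact minimizer of the penalized piecewise-linear cost.

    ``breakpoints`` contains segment boundaries as sample indices,
    including 0 and n: segment ``i`` covers samples
    ``[breakpoints[i], breakpoints[i+1])``.  ``fits[i]`` holds
    (slope_h, intercept_h, slope_v, intercept_v) of the per-axis
    least-squares lines (time referenced to the window start).
    """

    breakpoints: np.ndarray
    fits: np.ndarray
    cost: float
    penalty: float

    @property
    def n_segments(self) -> int:
        return len(self.breakpoints) - 1


class _SegmentCost:
    """O(1) two-axis linear-fit SSE for any [i, j) via prefix sums."""

    def __init__(self, t: np.ndarray, ys: Sequence[np.ndarray]):
        x = np.asarray(t, float)
        x = x - x[0]  # conditioning
        self.x = x
        self.ys = [np.asarray(y, float) for y in ys]
        z = np.zeros(1)
        self.px = np.concatenate([z, np.cumsum(x)])
        self.pxx = np.concatenate([z, np.cumsum(x * x)])
        self.py = [np.concatenate([z, np.cumsum(y)]) for y in self.ys]
        self.pyy = [np.concatenate([z, np.cumsum(y * y)]) for y in self.ys]
        self.pxy = [np.concatenate([z, np.cumsum(x * y)]) for y in self.ys]

    def sse(self, i, j):
        """Summed-over-axes SSE of per-axis LS lines on [i, j); vectorized in i."""
        i = np.asarray(i)
        n = (j - i).astype(float) if i.ndim else float(j - i)
        sx = self.px[j] - self.px[i]
        sxx = self.pxx[j] - self.pxx[i]
        cxx = sxx - sx * sx / n
        total = 0.0
        for py, pyy, pxy in zip(self.py, self.pyy, self.pxy):
            sy = py[j] - py[i]
            syy = pyy[j] - pyy[i]
            sxy = pxy[j] - pxy[i]
            cyy = syy - sy * sy / n
            cxy = sxy - sx * sy / n
            with np.errstate(divide="ignore", invalid="ignore"):
                fit = np.where(cxx > 1e-12, cxy * cxy / np.where(cxx > 0, cxx, 1.0), 0.0)
            total = total + np.maximum(cyy - fit, 0.0)
        return total

    def line(self, i: int, j: int, axis: int) -> Tuple[float, float]:
        """(slope, intercept) of the LS line for one axis on [i, j)."""
        n = float(j - i)
        sx = self.px[j] - self.px[i]
        sxx = self.pxx[j] - self.pxx[i]
        sy = self.py[axis][j] - self.py[axis][i]
        sxy = self.pxy[axis][j] - self.pxy[axis][i]
        cxx = sxx - sx * sx / n
        cxy = sxy - sx * sy / n
        slope = cxy / cxx if cxx > 1e-12 else 0.0
        intercept = (sy - slope * sx) / n
        return slope, intercept


def partition_signal(
    t: np.ndarray,
    gh: np.ndarray,
    gv: np.ndarray,
    penalty: float,
    min_size: int = MIN_SEGMENT_SAMPLES,
) -> PartitionSolution:
    """Exact optimal partition of a 2-D gaze trace into linear segments.

    Dynamic programming over all breakpoint placements with segments of
    at least ``min_size`` samples; deterministic, O(n²).  Raises
    ``ValueError`` for traces shorter than ``min_size``.
    """
    t = np.asarray(t, float)
    n = len(t)
    if n < min_size or n < 2:
        raise ValueError(f"trace has {n} samples; need at least {max(min_size, 2)}")
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    costs = _SegmentCost(t, (gh, gv))

    best = np.full(n + 1, np.inf)
    best[0] = 0.0
    prev = np.zeros(n + 1, dtype=int)
    for j in range(min_size, n + 1):
        i_cand = np.arange(0, j - min_size + 1)
        # a breakpoint at i requires best[i] finite (i = 0 or >= min_size)
        total = best[i_cand] + costs.sse(i_cand, j) + penalty
        k = int(np.argmin(total))
        best[j] = total[k]
        prev[j] = i_cand[k]

    bps = [n]
    while bps[-1] > 0:
        bps.append(int(prev[bps[-1]]))
    breakpoints = np.array(bps[::-1], dtype=int)
    fits = np.array(
        [
            costs.line(i, j, 0) + costs.line(i, j, 1)
            for i, j in zip(breakpoints[:-1], breakpoints[1:])
        ]
    )
    return PartitionSolution(
        breakpoints=breakpoints, fits=fits, cost=float(best[n]), penalty=penalty
    )


def robust_noise_sd(y: np.ndarray) -> float:
    """Noise SD estimate from median absolute first differences.

    For white noise the first difference has SD σ√2 and the MAD-based
    scale is |diff| median / 0.6745; slow linear trends barely move it.
    """
    d = np.abs(np.diff(np.asarray(y, float)))
    if d.size == 0:
        return 0.0
    return float(np.median(d) / (0.6745 * math.sqrt(2.0)))


def select_penalty(
    t: np.ndarray,
    gh: np.ndarray,
    gv: np.ndarray,
    c: float = DEFAULT_PENALTY_CONSTANT,
    sigma_floor: float = SIGMA_FLOOR,
) -> float:
    """Data-driven segmentation penalty: ``c · σ̂² · log n``.

    σ̂ is the RMS of the per-axis robust noise estimates (floored at
    ``sigma_floor`` so noiseless traces still get a positive penalty).
    The log n factor is the usual model-selection scaling of a
    per-breakpoint cost.
    """
    n = len(np.asarray(t))
    if n < 2:
        raise ValueError("need at least 2 samples")
    s_h = robust_noise_sd(gh)
    s_v = robust_noise_sd(gv)
    sigma2 = max((s_h * s_h + s_v * s_v) / 2.0, sigma_floor * sigma_floor)
    return float(c * sigma2 * math.log(max(n, 2)))


@dataclass(frozen=True)
class GazeSegment:
    """One detected linear gaze segment with its velocity summary."""

    start_s: float
    end_s: float
    duration: float
    n_samples: int
    slope_h: float  # deg/s
    slope_v: float  # deg/s
    amp_h: float  # deg, fitted(end) - fitted(start)
    amp_v: float  # deg
    speed: float  # deg/s, |amplitude| / duration
    direction: float  # deg from vehicle-frame vertical (0 = up, +cw)
    klass: str  # slow_phase | saccade | discarded
    yaw_mean: float  # deg/s over the segment


def segment_velocity(
    t: np.ndarray, gh: np.ndarray, gv: np.ndarray
) -> Tuple[Tuple[float, float], Tuple[float, float], float, float]:
    """Velocity summary of one segment from per-axis least squares.

    Returns ``((slope_h, slope_v), (amp_h, amp_v), speed, direction)``.
    Amplitude is the difference of the fitted line's values at the
    segment's first and last sample times ("calculated extremes"), so
    ``amp = slope · duration`` and ``speed = |amp| / duration``.
    Direction: 0° = upward in the vehicle frame, positive clockwise
    (rightward); downward-left motion maps to (−180°, −90°).
    """
    t = np.asarray(t, float)
    if len(t) < 2:
        raise ValueError("segment needs at least 2 samples")
    duration = float(t[-1] - t[0])
    if duration <= 0:
        raise ValueError("segment duration must be positive")
    x = t - t[0]
    slope_h, _ = np.polyfit(x, np.asarray(gh, float), 1)
    slope_v, _ = np.polyfit(x, np.asarray(gv, float), 1)
    amp_h = float(slope_h * duration)
    amp_v = float(slope_v * duration)
    speed = math.hypot(amp_h, amp_v) / duration
    # vertical axis is below-horizon-positive; upward on screen is -amp_v
    direction = math.degrees(math.atan2(amp_h, -amp_v))
    return (
        (float(slope_h), float(slope_v)),
        (amp_h, amp_v),
        float(speed),
        float(direction),
    )


def classify_segments(
    solution: PartitionSolution,
    t: np.ndarray,
    gh: np.ndarray,
    gv: np.ndarray,
    yaw: Optional[np.ndarray] = None,
    speed_threshold: float = DEFAULT_SACCADE_THRESHOLD,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    transition_guard: int = 1,
) -> List[GazeSegment]:
    """Turn an optimal partition into classified gaze segments.

    Segments with fewer than ``min_samples`` samples are ``discarded``
    (they are too short for a reliable velocity estimate — 12 samples is
    200 ms at 60 Hz); of the rest, fitted speed ≥ ``speed_threshold``
    marks a ``saccade`` and anything slower a ``slow_phase``.

    At tracker-noise levels where a one-to-two-sample quick phase does
    not pay for its own segment, the optimal partition places the
    breakpoint *inside* the quick phase, leaving one transition sample
    attached to each neighbouring slow phase; because quick phases
    always reset against the pursuit direction this tilts the fitted
    slope systematically toward zero.  ``transition_guard`` samples are
    therefore excluded at each end of a segment before fitting (the
    slope is estimated from the segment interior; amplitude is the
    fitted line evaluated at the segment's extreme times, so
    ``speed = |amplitude| / duration`` still holds).  Guarding is
    skipped when the segment is too short to leave two interior samples.
    """
    t = np.asarray(t, float)
    yaw = np.zeros_like(t) if yaw is None else np.asarray(yaw, float)
    out: List[GazeSegment] = []
    for i, j in zip(solution.breakpoints[:-1], solution.breakpoints[1:]):
        seg_t, seg_h, seg_v = t[i:j], gh[i:j], gv[i:j]
        if j - i < 2 or seg_t[-1] <= seg_t[0]:
            continue
        g = transition_guard if (j - i) - 2 * transition_guard >= 2 else 0
        sl = slice(g, (j - i) - g if g else None)
        (sh, sv), _, _, _ = segment_velocity(seg_t[sl], seg_h[sl], seg_v[sl])
        duration = float(seg_t[-1] - seg_t[0])
        ah, av = sh * duration, sv * duration
        speed = float(np.hypot(ah, av) / duration)
        direction = float(np.degrees(np.arctan2(ah, -av)))
        if j - i < min_samples:
            klass = "discarded"
        elif speed >= speed_threshold:
            klass = "saccade"
        else:
            klass = "slow_phase"
        out.append(
            GazeSegment(
                start_s=float(seg_t[0]),
                end_s=float(seg_t[-1]),
                duration=float(seg_t[-1] - seg_t[0]),
                n_samples=int(j - i),
                slope_h=sh,
                slope_v=sv,
                amp_h=ah,
                amp_v=av,
                speed=speed,
                direction=direction,
                klass=klass,
                yaw_mean=float(np.mean(yaw[i:j])),
            )
        )
    return out


def split_on_gaps(valid: np.ndarray, min_len: int = DEFAULT_MIN_SAMPLES):
    """Contiguous runs of valid samples, dropping runs shorter than ``min_len``.

    Excluded samples break the trace into independent windows; windows
    too short to ever yield a retainable segment are skipped entirely.
    Yields ``(start, stop)`` index pairs.
    """
    valid = np.asarray(valid, bool)
    n = len(valid)
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j < n and valid[j]:
            j += 1
        if j - i >= min_len:
            yield i, j
        i = j
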