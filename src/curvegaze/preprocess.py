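"""Quality filtering, multirate resampling, route alignment, phase labels.

The raw trial record mixes three sample rates (60 Hz gaze, 100 Hz CAN,
1 Hz GPS).  Analysis happens on the 60 Hz gaze timebase within a
location-based representation: every sample is assigned a distance along
the route by matching its position to a prototype trial, and the bend is
split into *approach*, *entry* ([onset − 50 m, onset)) and *cornering*
([onset, offset − 35 m]) phases.  Samples are flagged, never deleted, so
exclusion reasons stay auditable.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import BendGeometry
from .synthetic import TrialRecord

__all__ = [
    "DEFAULT_QUALITY_THRESHOLD",
    "ALIGNMENT_MAX_DIST_M",
    "quality_filter",
    "upsample_linear",
    "downsample_nearest",
    "resample",
    "align_to_prototype",
    "segment_bend",
    "align_trial",
]

DEFAULT_QUALITY_THRESHOLD = 0.2
#: nearest-neighbour distance beyond which prototype matching is flagged
ALIGNMENT_MAX_DIST_M = 25.0


def quality_filter(
    trial: TrialRecord, threshold: float = DEFAULT_QUALITY_THRESHOLD
) -> TrialRecord:
    """Flag gaze samples whose tracker quality falls below ``threshold``.

    The criterion is strict (<): a sample exactly at the threshold is
    retained.  Flagged samples get ``excluded=True`` and reason code
    ``"quality"``; nothing is deleted.
    """
    out = trial.copy()
    q = out.gaze["quality"].to_numpy()
    bad = q < threshold
    excl = out.gaze.get("excluded")
    prev = excl.to_numpy(dtype=bool) if excl is not None else np.zeros(len(q), bool)
    out.gaze["excluded"] = prev | bad
    reasons = out.gaze.get("excl_reason")
    reason = (
        reasons.to_numpy(dtype=object)
        if reasons is not None
        else np.full(len(q), "", dtype=object)
    )
    reason[bad] = "quality"
    out.gaze["excl_reason"] = reason
    return out


def upsample_linear(t_src, y_src, t_target) -> np.ndarray:
    """Linear interpolation at ``t_target`` with clamped endpoints."""
    t_src = np.asarray(t_src, float)
    y_src = np.asarray(y_src, float)
    if t_src.size == 0:
        raise ValueError("empty source series")
    return np.interp(np.asarray(t_target, float), t_src, y_src)


def downsample_nearest(t_src, y_src, t_target) -> np.ndarray:
    """Nearest-preceding-sample selection at ``t_target`` (clamped)."""
    t_src = np.asarray(t_src, float)
    y_src = np.asarray(y_src)
    if t_src.size == 0:
        raise ValueError("empty source series")
    idx = np.searchsorted(t_src, np.asarray(t_target, float), side="right") - 1
    return y_src[np.clip(idx, 0, len(t_src) - 1)]


def resample(
    t_src, y_src, target_rate: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Resample a time series to a uniform ``target_rate``.

    Upsampling interpolates linearly over the full span (endpoint
    included, so a round trip through a faster grid is lossless);
    downsampling selects the nearest preceding source sample — how a
    logger synchronizing a faster stream to a slower clock behaves —
    on a grid of ``ceil(duration · target_rate)`` points (minimum 1).
    Both grids start at the first source timestamp.
    """
    t_src = np.asarray(t_src, float)
    if t_src.size == 0:
        raise ValueError("empty source series")
    if target_rate <= 0:
        raise ValueError("target_rate must be > 0")
    duration = float(t_src[-1] - t_src[0])
    src_rate = (len(t_src) - 1) / duration if duration > 0 else np.inf
    if target_rate > src_rate:
        n = int(np.floor(duration * target_rate + 1e-9)) + 1
        t_new = t_src[0] + np.arange(n) / target_rate
        y_new = upsample_linear(t_src, y_src, t_new)
    else:
        n = max(1, int(np.ceil(duration * target_rate)))
        t_new = t_src[0] + np.arange(n) / target_rate
        y_new = downsample_nearest(t_src, y_src, t_new)
    return t_new, y_new


def align_to_prototype(
    trial_xy: np.ndarray,
    proto_xy: np.ndarray,
    max_dist: float = ALIGNMENT_MAX_DIST_M,
) -> Tuple[np.ndarray, np.ndarray]:
    """Along-route distance of each trial sample via the prototype trace.

    Each sample takes the cumulative arc-length of its Euclidean nearest
    neighbour on the prototype; the result is made non-decreasing by a
    running maximum.  Samples whose nearest neighbour is farther than
    ``max_dist`` are flagged as alignment failures.

    Returns ``(dist_m, failed)``.
    """
    trial_xy = np.asarray(trial_xy, float)
    proto_xy = np.asarray(proto_xy, float)
    if proto_xy.ndim != 2 or len(proto_xy) < 2:
        raise ValueError("prototype must contain at least 2 positions")
    steps = np.hypot(*np.diff(proto_xy, axis=0).T)
    cumdist = np.concatenate([[0.0], np.cumsum(steps)])
    nn_dist, idx = cKDTree(proto_xy).query(trial_xy)
    dist = np.maximum.accumulate(cumdist[idx])
    return dist, nn_dist > max_dist


def segment_bend(
    dist_m: np.ndarray,
    bend: BendGeometry,
    onset_dist: float,
    approach_start: Optional[float] = None,
) -> np.ndarray:
    """Phase label per sample from along-route distance.

    entry = [onset − entry_length, onset); cornering = [onset,
    onset + arc − exit_cutoff] (closed end); approach precedes entry
    from ``approach_start`` (default: from the first sample).  All other
    samples are labelled ``excluded``.
    """
    arc = bend.cornering_arc_length
    if arc <= bend.exit_cutoff:
        raise ValueError("cornering arc must exceed the exit cutoff")
    d = np.asarray(dist_m, float)
    entry_start = onset_dist - bend.entry_length
    corner_end = onset_dist + arc - bend.exit_cutoff
    if approach_start is None:
        approach_start = -np.inf
    labels = np.full(len(d), "excluded", dtype=object)
    labels[(d >= approach_start) & (d < entry_start)] = "approach"
    labels[(d >= entry_start) & (d < onset_dist)] = "entry"
    labels[(d >= onset_dist) & (d <= corner_end)] = "cornering"
    return labels


def align_trial(
    trial: TrialRecord,
    prototype: Optional[TrialRecord] = None,
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
) -> pd.DataFrame:
    """Full per-trial preprocessing onto the 60 Hz gaze timebase.

    Applies the quality filter, merges the CAN stream (nearest preceding
    sample) and GPS (linear interpolation) onto gaze timestamps, assigns
    along-route distance by prototype matching (the trial itself if no
    prototype is given) and labels bend phases.  Returns the aligned
    frame with columns ``dist_m``, ``phase``, ``excluded`` and
    ``excl_reason`` added.
    """
    filt = quality_filter(trial, quality_threshold)
    frame = filt.to_frame()
    frame["excluded"] = filt.gaze["excluded"].to_numpy()
    frame["excl_reason"] = filt.gaze["excl_reason"].to_numpy()
    if trial.meta.get("traffic"):
        frame["excluded"] = True
        frame["excl_reason"] = "traffic"
    if trial.meta.get("weather"):
        frame["excluded"] = True
        frame["excl_reason"] = "weather"

    proto = prototype if prototype is not None else trial
    tg = proto.gps["t"].to_numpy()
    t60 = proto.gaze["t"].to_numpy()
    proto_xy = np.column_stack(
        [
            upsample_linear(tg, proto.gps["x_m"].to_numpy(), t60),
            upsample_linear(tg, proto.gps["y_m"].to_numpy(), t60),
        ]
    )
    trial_xy = frame[["x_m", "y_m"]].to_numpy()
    dist, failed = align_to_prototype(trial_xy, proto_xy)
    frame["dist_m"] = dist
    if failed.any():
        frame.loc[failed, "excluded"] = True
        frame.loc[failed, "excl_reason"] = "alignment"

    onset = proto.meta.get("onset_dist_m", trial.meta.get("onset_dist_m", 0.0))
    frame["phase"] = segment_bend(dist, trial.bend, onset)
    return frame
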