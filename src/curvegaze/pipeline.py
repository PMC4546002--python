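"""End-to-end orchestration: trial → aligned frame → segments → report.

``detect_trial`` runs the per-trial chain (quality filter, multirate
merge, prototype alignment, phase labels, optimal partitioning,
classification); ``analyze_segments`` aggregates the fixation-by-
fixation Δ statistic into per-subject means, confidence intervals and
condition contrasts, plus the descriptive summaries (direction
histograms, velocity-density thresholds, tangent-point displacement
medians).
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel

from . import oknstats, preprocess, semdetect
from .synthetic import TrialRecord

__all__ = [
    "DetectParams",
    "AnalysisParams",
    "detect_trial",
    "detect_cohort",
    "segment_stats_frame",
    "classify_trial_conditions",
    "analyze_segments",
]

log = logging.getLogger("curvegaze")

SEGMENT_COLUMNS = [
    "subject", "trial", "condition", "bend_id", "handedness", "phase",
    "t_start", "t_end", "duration", "n", "slope_h", "slope_v",
    "amp_h", "amp_v", "speed", "direction", "class", "yaw_mean",
]


class DetectParams(BaseModel):
    """Detection-stage knobs (defaults follow the analysis conventions)."""

    model_config = {"frozen": True}

    quality_threshold: float = preprocess.DEFAULT_QUALITY_THRESHOLD
    penalty_constant: float = semdetect.DEFAULT_PENALTY_CONSTANT
    min_samples: int = semdetect.DEFAULT_MIN_SAMPLES
    saccade_threshold: float = semdetect.DEFAULT_SACCADE_THRESHOLD
    sigma_floor: float = semdetect.SIGMA_FLOOR
    transition_guard: int = 1


class AnalysisParams(BaseModel):
    """Analysis-stage knobs."""

    model_config = {"frozen": True}

    n_bins: int = 36
    mass_fractions: Tuple[float, ...] = (0.25, 0.5, 0.75)
    confidence: float = 0.95


def detect_trial(
    trial: TrialRecord,
    params: DetectParams = DetectParams(),
    prototype: Optional[TrialRecord] = None,
) -> Tuple[pd.DataFrame, Dict]:
    """Detect and classify gaze segments in one trial.

    Windows are contiguous runs of non-excluded samples within a single
    phase; each window is partitioned independently with a data-driven
    penalty.  Returns the segments table and a per-trial summary with
    the median tangent-point displacement over cornering.
    """
    frame = preprocess.align_trial(trial, prototype, params.quality_threshold)
    handed = trial.bend.bend_handedness
    valid = (~frame["excluded"].to_numpy()) & (
        frame["phase"].to_numpy() != "excluded"
    )
    phases = frame["phase"].to_numpy()
    t = frame["t"].to_numpy()
    gh = frame["gh_deg"].to_numpy()
    gv = frame["gv_deg"].to_numpy()
    yaw = frame["yaw_dps"].to_numpy()

    rows: List[Dict] = []
    # phase changes also break windows so every segment has one phase
    codes = pd.factorize(phases)[0]
    boundary = np.r_[True, np.diff(codes) != 0]
    run_id = np.cumsum(boundary)
    key = run_id * 2 + valid.astype(int)
    for i, j in _runs(key):
        if not valid[i] or j - i < params.min_samples:
            continue
        penalty = semdetect.select_penalty(
            t[i:j], gh[i:j], gv[i:j],
            c=params.penalty_constant, sigma_floor=params.sigma_floor,
        )
        sol = semdetect.partition_signal(t[i:j], gh[i:j], gv[i:j], penalty)
        segs = semdetect.classify_segments(
            sol, t[i:j], gh[i:j], gv[i:j], yaw[i:j],
            speed_threshold=params.saccade_threshold,
            min_samples=params.min_samples,
            transition_guard=params.transition_guard,
        )
        for s in segs:
            rows.append(
                {
                    "subject": trial.subject,
                    "trial": trial.trial,
                    "condition": trial.condition,
                    "bend_id": trial.bend_id,
                    "handedness": handed,
                    "phase": phases[i],
                    "t_start": s.start_s,
                    "t_end": s.end_s,
                    "duration": s.duration,
                    "n": s.n_samples,
                    "slope_h": s.slope_h,
                    "slope_v": s.slope_v,
                    "amp_h": s.amp_h,
                    "amp_v": s.amp_v,
                    "speed": s.speed,
                    "direction": s.direction,
                    "class": s.klass,
                    "yaw_mean": s.yaw_mean,
                }
            )
    segments = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)

    corner = (phases == "cornering") & ~frame["excluded"].to_numpy()
    _, med = oknstats.tp_displacement(frame, corner)
    summary = {
        "subject": trial.subject,
        "trial": trial.trial,
        "condition": trial.condition,
        "bend_id": trial.bend_id,
        "handedness": handed,
        "n_segments": len(segments),
        "n_slow_phase": int((segments["class"] == "slow_phase").sum()),
        "n_excluded_samples": int(frame["excluded"].sum()),
        "median_tp_dh_deg": med[0],
        "median_tp_dv_deg": med[1],
        "mean_abs_yaw_cornering": float(np.mean(np.abs(yaw[corner])))
        if corner.any()
        else float("nan"),
        "truncated": bool(trial.meta.get("truncated", False)),
    }
    return segments, summary


def _runs(key: np.ndarray):
    """(start, stop) of constant-key runs."""
    n = len(key)
    i = 0
    while i < n:
        j = i
        while j < n and key[j] == key[i]:
            j += 1
        yield i, j
        i = j


def detect_cohort(
    trials: Sequence[TrialRecord],
    params: DetectParams = DetectParams(),
    prototype: Optional[TrialRecord] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Detect segments for a cohort against a common prototype trial.

    The prototype defaults to the first trial.  Returns the concatenated
    segments table and the trial-summary table.
    """
    if not trials:
        raise ValueError("no trials")
    proto = prototype if prototype is not None else trials[0]
    all_segments, summaries = [], []
    for trial in trials:
        segs, summ = detect_trial(trial, params, proto)
        log.info(
            "detected s%02d t%02d %s: %d segments (%d slow phases)",
            trial.subject, trial.trial, trial.condition,
            len(segs), summ["n_slow_phase"],
        )
        all_segments.append(segs)
        summaries.append(summ)
    segments = pd.concat(all_segments, ignore_index=True)
    return segments, pd.DataFrame(summaries)


def segment_stats_frame(segments: pd.DataFrame) -> pd.DataFrame:
    """Fixation-by-fixation Δ for cornering slow phases.

    Vectorized equivalent of :func:`curvegaze.oknstats.velocity_statistic`
    over a segments table: Δ = ½|yaw_mean| − v_against with v_against
    the against-bend horizontal slope.
    """
    sel = segments[
        (segments["class"] == "slow_phase") & (segments["phase"] == "cornering")
    ].copy()
    sign = np.where(sel["handedness"].to_numpy() == "right", -1.0, 1.0)
    sel["v_against"] = sign * sel["slope_h"].to_numpy()
    sel["half_yaw"] = 0.5 * np.abs(sel["yaw_mean"].to_numpy())
    sel["delta"] = sel["half_yaw"] - sel["v_against"]
    return sel


def classify_trial_conditions(stats: pd.DataFrame) -> pd.DataFrame:
    """Predict each trial's condition from its mean Δ.

    A trial whose mean Δ exceeds half its own predicted tangent-point
    value (½ × mean ½|yaw|) is classified ``tp``, else ``normal``.
    Returns one row per trial with the truth, prediction and mean Δ.
    """
    if stats.empty:
        raise ValueError("no slow-phase statistics")
    rows = []
    for (subj, trial), sub in stats.groupby(["subject", "trial"]):
        mean_delta = float(sub["delta"].mean())
        threshold = 0.5 * float(sub["half_yaw"].mean())
        rows.append(
            {
                "subject": subj,
                "trial": trial,
                "condition": sub["condition"].iloc[0],
                "mean_delta": mean_delta,
                "predicted": "tp" if mean_delta > threshold else "normal",
            }
        )
    out = pd.DataFrame(rows)
    out["correct"] = out["predicted"] == out["condition"].where(
        out["condition"].isin(["normal", "tp"]), "normal"
    )
    return out


def analyze_segments(
    segments: pd.DataFrame,
    summaries: Optional[pd.DataFrame] = None,
    params: AnalysisParams = AnalysisParams(),
) -> Dict:
    """Aggregate a segments table into the full analysis report.

    Contains the group inference on Δ, per-condition direction
    histograms and velocity-density (HDR) thresholds, tangent-point
    displacement medians per subject, and every parameter used.
    """
    stats = segment_stats_frame(segments)
    report: Dict = {
        "parameters": params.model_dump(),
        "n_segments": int(len(segments)),
        "n_slow_phase_cornering": int(len(stats)),
    }
    if stats.empty:
        report["status"] = "empty"
        return report
    report["status"] = "ok"

    gr = oknstats.group_inference(
        stats[["subject", "condition", "delta"]], confidence=params.confidence
    )
    report["group_result"] = gr.to_dict()

    histograms = {}
    hdr = {}
    for cond, sub in stats.groupby("condition"):
        freqs, edges = oknstats.direction_histogram(
            sub["direction"].to_list(), params.n_bins
        )
        histograms[cond] = {"freqs": freqs.tolist(), "edges": edges.tolist()}
        vel = sub[["slope_h", "slope_v"]].to_numpy()
        if len(vel) >= 30:
            thr, _ = oknstats.hdr_mass_threshold(vel, params.mass_fractions)
            hdr[cond] = {str(p): v for p, v in thr.items()}
    report["direction_histograms"] = histograms
    report["hdr_thresholds"] = hdr

    if summaries is not None and not summaries.empty:
        med = (
            summaries.groupby(["condition", "subject"])[
                ["median_tp_dh_deg", "median_tp_dv_deg"]
            ]
            .median()
            .reset_index()
        )
        report["tp_displacement_medians"] = med.to_dict(orient="records")

    try:
        cls = classify_trial_conditions(stats)
        report["condition_classification"] = {
            "accuracy": float(cls["correct"].mean()),
            "n_trials": int(len(cls)),
        }
    except ValueError:
        pass
    return report
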