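"""Descriptive and inferential statistics of optokinetic slow phases.

The discriminating quantity between the two steering-gaze hypotheses is
computed fixation by fixation: for each detected slow phase,

    Δ = ½·|mean yaw rate| − v_against

where ``v_against`` is the horizontal slow-phase velocity component
directed *against* the bend (positive when gaze moves opposite to the
turn, as the optic flow at future-path points does).  Perfect waypoint
tracking gives v_against = ½|yaw| and hence Δ = 0; perfect tangent-point
fixation gives v_against = 0 and Δ = +½|yaw|.  The orientation is chosen
so the tangent-point condition comes out positive; the statistic is
invariant under mirroring the bend handedness.

Per-subject means of Δ are aggregated per condition; inference uses
t-based 95% confidence intervals, a paired t-test for the within-subject
normal-vs-tp contrast and a pooled-variance independent t-test against a
separate control group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .semdetect import GazeSegment

__all__ = [
    "SegmentStat",
    "GroupResult",
    "tp_displacement",
    "direction_histogram",
    "velocity_statistic",
    "group_inference",
    "hdr_mass_threshold",
]


@dataclass(frozen=True)
class SegmentStat:
    """Per-slow-phase Δ statistic with its grouping keys."""

    subject: int
    condition: str
    bend_id: int
    delta: float  # deg/s
    v_against: float  # deg/s
    half_yaw: float  # deg/s
    duration: float  # s


def velocity_statistic(
    segment: GazeSegment, bend_handedness: str, *,
    subject: int = 0, condition: str = "", bend_id: int = 0,
) -> SegmentStat:
    """Δ = ½·|mean yaw| − against-bend horizontal slow-phase velocity.

    Only meaningful for ``slow_phase`` segments inside the cornering
    phase (the caller filters); raises ``ValueError`` otherwise.  With
    rightward-positive horizontal velocity, against-bend is leftward
    (−slope) in a right-hand bend and rightward (+slope) in a left-hand
    one.
    """
    if segment.klass != "slow_phase":
        raise ValueError("velocity statistic is defined for slow phases only")
    sign = -1.0 if bend_handedness == "right" else 1.0
    v_against = sign * segment.slope_h
    half_yaw = 0.5 * abs(segment.yaw_mean)
    delta = half_yaw - v_against
    if not np.isfinite(delta):
        raise ValueError("non-finite velocity statistic")
    return SegmentStat(
        subject=subject,
        condition=condition,
        bend_id=bend_id,
        delta=float(delta),
        v_against=float(v_against),
        half_yaw=float(half_yaw),
        duration=segment.duration,
    )


def tp_displacement(
    frame: pd.DataFrame, mask: Optional[np.ndarray] = None
) -> Tuple[pd.DataFrame, Tuple[float, float]]:
    """Gaze displacement from the tangent point, per sample and its median.

    ``frame`` must carry gaze (gh_deg, gv_deg) and per-sample TP
    direction (tp_h_deg, tp_v_deg).  Returns the per-sample displacement
    frame and the component-wise median over ``mask`` (default: all
    samples).  The median is robust: symmetric tracker noise moves it
    very little.
    """
    disp = pd.DataFrame(
        {
            "t": frame["t"].to_numpy(),
            "dh_deg": frame["gh_deg"].to_numpy() - frame["tp_h_deg"].to_numpy(),
            "dv_deg": frame["gv_deg"].to_numpy() - frame["tp_v_deg"].to_numpy(),
        }
    )
    m = np.ones(len(disp), bool) if mask is None else np.asarray(mask, bool)
    if m.sum() == 0:
        return disp, (float("nan"), float("nan"))
    med = (
        float(np.median(disp["dh_deg"].to_numpy()[m])),
        float(np.median(disp["dv_deg"].to_numpy()[m])),
    )
    return disp, med


def direction_histogram(
    directions: Sequence[float], n_bins: int = 36
) -> Tuple[np.ndarray, np.ndarray]:
    """Relative-frequency histogram of segment directions.

    Equal-width bins over (−180°, 180°]; frequencies sum to exactly 1.
    Raises ``ValueError`` on empty input.
    """
    d = np.asarray(directions, float)
    if d.size == 0:
        raise ValueError("no segments to histogram")
    # map to (-180, 180]
    d = -((-d + 180.0) % 360.0 - 180.0)
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    idx = np.clip(np.ceil((d + 180.0) / 360.0 * n_bins).astype(int) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return counts / counts.sum(), edges


def _t_ci(values: np.ndarray, confidence: float) -> Tuple[float, float]:
    n = len(values)
    m = float(np.mean(values))
    se = float(np.std(values, ddof=1) / np.sqrt(n))
    tcrit = float(sps.t.ppf(0.5 + confidence / 2.0, n - 1))
    return m - tcrit * se, m + tcrit * se


@dataclass
class GroupResult:
    """Per-condition subject means with CIs and condition contrasts."""

    subject_means: Dict[str, Dict[int, float]]
    group_means: Dict[str, float]
    cis: Dict[str, Tuple[float, float]]
    paired_test: Optional[Dict] = None  # normal vs tp, within subjects
    independent_test: Optional[Dict] = None  # normal vs control, pooled var
    pooled_ci: Optional[Tuple[float, float]] = None  # normal + control
    confidence: float = 0.95

    def to_dict(self) -> Dict:
        return {
            "subject_means": {
                c: {str(s): v for s, v in d.items()}
                for c, d in self.subject_means.items()
            },
            "group_means": self.group_means,
            "cis": {c: list(ci) for c, ci in self.cis.items()},
            "paired_test": self.paired_test,
            "independent_test": self.independent_test,
            "pooled_ci": list(self.pooled_ci) if self.pooled_ci else None,
            "confidence": self.confidence,
        }


def group_inference(
    stats: Iterable[SegmentStat] | pd.DataFrame,
    confidence: float = 0.95,
) -> GroupResult:
    """Per-subject aggregation and condition contrasts of Δ.

    Subject means are unweighted means of Δ over all of a subject's slow
    phases within a condition.  Each condition gets a t-based CI
    (df = n_subjects − 1).  If both ``normal`` and ``tp`` are present, a
    paired two-sided t-test over common subjects is run; if ``control``
    is present, an independent pooled-variance t-test of normal vs
    control (df = n1 + n2 − 2) and a pooled CI over the concatenated
    normal+control subject means.  Raises ``ValueError`` for conditions
    with fewer than 2 subjects.
    """
    if isinstance(stats, pd.DataFrame):
        df = stats
    else:
        df = pd.DataFrame(
            [
                {"subject": s.subject, "condition": s.condition, "delta": s.delta}
                for s in stats
            ]
        )
    if df.empty:
        raise ValueError("no segment statistics provided")
    subject_means: Dict[str, Dict[int, float]] = {}
    group_means: Dict[str, float] = {}
    cis: Dict[str, Tuple[float, float]] = {}
    for cond, sub in df.groupby("condition"):
        means = sub.groupby("subject")["delta"].mean()
        if len(means) < 2:
            raise ValueError(
                f"condition {cond!r} has {len(means)} subject(s); CI undefined"
            )
        subject_means[cond] = {int(s): float(v) for s, v in means.items()}
        group_means[cond] = float(means.mean())
        cis[cond] = _t_ci(means.to_numpy(), confidence)

    result = GroupResult(
        subject_means=subject_means,
        group_means=group_means,
        cis=cis,
        confidence=confidence,
    )

    if "normal" in subject_means and "tp" in subject_means:
        common = sorted(
            set(subject_means["normal"]) & set(subject_means["tp"])
        )
        if len(common) >= 2:
            a = np.array([subject_means["normal"][s] for s in common])
            b = np.array([subject_means["tp"][s] for s in common])
            if np.all(a == b):  # degenerate: no difference at all
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_rel(a, b)
            result.paired_test = {
                "contrast": "normal-tp",
                "t": float(t),
                "df": len(common) - 1,
                "p": float(p),
                "n": len(common),
            }
    if "normal" in subject_means and "control" in subject_means:
        a = np.array(list(subject_means["normal"].values()))
        b = np.array(list(subject_means["control"].values()))
        t, p = sps.ttest_ind(a, b, equal_var=True)
        result.independent_test = {
            "contrast": "normal-control",
            "t": float(t),
            "df": len(a) + len(b) - 2,
            "p": float(p),
            "n1": len(a),
            "n2": len(b),
        }
        result.pooled_ci = _t_ci(np.concatenate([a, b]), confidence)
    return result


def hdr_mass_threshold(
    samples: np.ndarray,
    mass_fractions: Sequence[float],
    grid_size: int = 64,
):
    """Highest-density-region thresholds of a 2-D sample cloud.

    A Gaussian KDE (Scott bandwidth) is evaluated at the samples; for
    each requested mass fraction ``p`` the returned density level is the
    largest level whose superlevel set contains at least fraction ``p``
    of the samples (the nearest achievable enclosed mass).  Also returns
    a grid evaluation for contour plotting.

    Returns ``(thresholds: dict p -> level, (gx, gy, gz))``.
    """
    pts = np.asarray(samples, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("samples must be (n, 2)")
    if len(pts) < 30:
        raise ValueError("need at least 30 samples for a density estimate")
    kde = sps.gaussian_kde(pts.T)
    dens = kde(pts.T)
    order = np.sort(dens)
    n = len(order)
    thresholds = {}
    for p in mass_fractions:
        if not (0 < p <= 1):
            raise ValueError("mass fractions must be in (0, 1]")
        # highest level keeping at least fraction p of samples above it
        k = int(np.floor(n * (1.0 - p)))
        thresholds[float(p)] = float(order[min(k, n - 1)])
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    pad = 0.1 * (hi - lo + 1e-9)
    gx = np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid_size)
    gy = np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid_size)
    mx, my = np.meshgrid(gx, gy)
    gz = kde(np.vstack([mx.ravel(), my.ravel()])).reshape(mx.shape)
    return thresholds, (gx, gy, gz)
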