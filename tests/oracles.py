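"""Independent oracles used by the test suite.

These deliberately avoid the package's own algebra: segment fits come
from numpy.polyfit and the partition search enumerates compositions
explicitly, so they can arbitrate the dynamic-programming solver.
"""

import numpy as np


def exhaustive_partition_cost(t, gh, gv, penalty, min_size=2):
    """Minimum of Σ SSE + penalty·k over every partition with ≥min_size parts.

    Enumerates all compositions of n into segments of at least
    ``min_size`` samples (Fibonacci-many, fine for n ≤ 20) and scores
    each against a polyfit-based SSE table.
    """
    t = np.asarray(t, float)
    n = len(t)
    sse = np.full((n + 1, n + 1), np.nan)
    for i in range(n):
        for j in range(i + min_size, n + 1):
            x = t[i:j] - t[i]
            total = 0.0
            for y in (gh[i:j], gv[i:j]):
                coef = np.polyfit(x, y, 1)
                total += float(np.sum((y - np.polyval(coef, x)) ** 2))
            sse[i, j] = total

    best = [np.inf]

    def extend(start, cost):
        if cost >= best[0]:
            return
        for j in range(start + min_size, n + 1):
            if j != n and n - j < min_size:
                continue
            c = cost + sse[start, j] + penalty
            if j == n:
                best[0] = min(best[0], c)
            else:
                extend(j, c)

    extend(0, 0.0)
    return best[0]


def slow_phase_overlap_fraction(trials, segments):
    """Fraction of ground-truth slow phases covered ≥ 50% by a detection.

    A ground-truth slow phase counts as recovered when some detected
    ``slow_phase`` segment of the same trial overlaps at least half of
    its duration.  Only events inside the analyzed cornering window are
    scored: detection deliberately stops at the exit cutoff, so events
    in the final 35 m of the arc are outside every analysis window.
    """
    total, hit = 0, 0
    for trial in trials:
        speed = trial.meta["speed"]
        t_cut = (
            trial.meta["cornering_end_m"] - trial.bend.exit_cutoff
        ) / speed
        det = segments[
            (segments["subject"] == trial.subject)
            & (segments["trial"] == trial.trial)
            & (segments["class"] == "slow_phase")
        ]
        spans = list(zip(det["t_start"].to_numpy(), det["t_end"].to_numpy()))
        for e in trial.ground_truth:
            if e.kind != "slow_phase" or e.end_s <= e.start_s:
                continue
            if e.end_s > t_cut:
                continue
            total += 1
            need = 0.5 * (e.end_s - e.start_s)
            if any(
                min(e.end_s, b) - max(e.start_s, a) >= need for a, b in spans
            ):
                hit += 1
    return hit / total if total else 0.0
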