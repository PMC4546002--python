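#!/usr/bin/env python
"""Condition contrasts on the fixation-by-fixation Δ statistic.

Aggregates Δ = ½·|yaw| − v_against per subject and condition, reports
95% confidence intervals, the paired normal-vs-tp t-test, the
independent normal-vs-control contrast, the pooled CI and the per-trial
condition classification, and writes results/report.json.

Under waypoint (future-path) tracking Δ centres on zero; under
tangent-point fixation it centres on ½·|yaw| (≈ 7 deg/s at 42 km/h on a
48 m bend).

Usage:  python analysis/03_analyze.py [--out results]
"""

import argparse
import sys
from pathlib import Path

from curvegaze import AnalysisParams, analyze_segments
from curvegaze import io as cio


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    segments = cio.read_segments(args.out / "segments.tsv")
    summaries = cio.read_segments(args.out / "trial_summaries.tsv")
    report = analyze_segments(segments, summaries, AnalysisParams())
    cio.write_json(args.out / "report.json", report)

    gr = report["group_result"]
    print(f"slow phases analyzed: {report['n_slow_phase_cornering']}")
    for cond in ("normal", "tp", "control"):
        if cond in gr["group_means"]:
            lo, hi = gr["cis"][cond]
            print(
                f"  {cond:8s} mean Δ = {gr['group_means'][cond]:+.2f} deg/s, "
                f"95% CI [{lo:+.2f}, {hi:+.2f}]"
            )
    if gr.get("paired_test"):
        p = gr["paired_test"]
        print(f"  normal vs tp (paired):   t({p['df']}) = {p['t']:.2f}, p = {p['p']:.2g}")
    if gr.get("independent_test"):
        p = gr["independent_test"]
        print(f"  normal vs control (ind): t({p['df']}) = {p['t']:.2f}, p = {p['p']:.2g}")
    if gr.get("pooled_ci"):
        lo, hi = gr["pooled_ci"]
        print(f"  pooled normal+control 95% CI [{lo:+.2f}, {hi:+.2f}]")
    cc = report.get("condition_classification")
    if cc:
        print(
            f"  per-trial condition classification: "
            f"{100 * cc['accuracy']:.1f}% of {cc['n_trials']} trials"
        )
    print("report written to", args.out / "report.json", file=sys.stderr)


if __name__ == "__main__":
    main()
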