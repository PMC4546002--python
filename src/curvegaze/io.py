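"""File formats and provenance helpers.

Trials are written as CSV (one row per 60 Hz sample, comma-separated,
UTF-8, '.' decimal, header row mandatory; angles deg, distances m,
rates deg/s) with a sidecar JSON carrying trial metadata and the
ground-truth event log.  Every output file starts with a ``#`` comment
line carrying the software version and config hash; readers skip it.
See FORMATS.md at the repository root for the column reference.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
from pydantic import BaseModel

from . import __version__
from .synthetic import GroundTruthEvent, TrialRecord

__all__ = [
    "config_hash",
    "provenance_line",
    "write_trial",
    "read_trial",
    "trial_paths",
    "write_segments",
    "read_segments",
    "write_manifest",
    "write_json",
]

FLOAT_FORMAT = "%.6f"


def config_hash(config: BaseModel | Dict) -> str:
    """Short stable hash of a configuration (canonical JSON, sha256)."""
    payload = config.model_dump() if isinstance(config, BaseModel) else config
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]

def provenance_line(cfg_hash: str) -> str:
    return f"# curvegaze {__version__} config={cfg_hash}\n"


def _trial_stem(trial: TrialRecord) -> str:
    return f"trial_s{trial.subject:02d}_r{trial.trial:02d}"


def write_trial(out_dir: Path, trial: TrialRecord, cfg_hash: str = "") -> List[Path]:
    """Write one trial as CSV + ground-truth sidecar JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = _trial_stem(trial)
    csv_path = out_dir / f"{stem}.csv"
    frame = trial.to_frame()
    with open(csv_path, "w", encoding="utf-8") as fh:
        fh.write(provenance_line(cfg_hash))
        frame.to_csv(fh, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    side_path = out_dir / f"{stem}.json"
    sidecar = {
        "version": __version__,
        "config": cfg_hash,
        "subject": trial.subject,
        "trial": trial.trial,
        "condition": trial.condition,
        "bend_id": trial.bend_id,
        "meta": trial.meta,
        "ground_truth": [
            {"start_s": e.start_s, "end_s": e.end_s, "kind": e.kind,
             "target": e.target}
            for e in trial.ground_truth
        ],
    }
    side_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return [csv_path, side_path]


def read_trial(csv_path: Path) -> TrialRecord:
    """Read a trial CSV (+ sidecar) back into a :class:`TrialRecord`.

    The reconstructed record carries all streams on the 60 Hz timebase
    (the CSV is the merged representation); resampling of the merged
    columns is then an identity pass.
    """
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path, comment="#")
    required = {"t", "gh_deg", "gv_deg", "quality", "speed_mps", "yaw_dps",
                "x_m", "y_m"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{csv_path.name}: missing columns {sorted(missing)}")
    if frame.empty:
        raise ValueError(f"{csv_path.name}: no samples")
    side_path = csv_path.with_suffix(".json")
    sidecar = json.loads(side_path.read_text()) if side_path.exists() else {}
    gaze_cols = ["t", "gh_deg", "gv_deg", "quality"]
    for c in ("tp_h_deg", "tp_v_deg"):
        if c in frame.columns:
            gaze_cols.append(c)
    events = [
        GroundTruthEvent(e["start_s"], e["end_s"], e["kind"], e["target"])
        for e in sidecar.get("ground_truth", [])
    ]
    return TrialRecord(
        gaze=frame[gaze_cols].copy(),
        vehicle=frame[["t", "speed_mps", "yaw_dps"]].copy(),
        gps=frame[["t", "x_m", "y_m"]].copy(),
        subject=int(sidecar.get("subject", frame.get("subject", pd.Series([0]))[0])),
        trial=int(sidecar.get("trial", frame.get("trial", pd.Series([0]))[0])),
        condition=str(
            sidecar.get("condition", frame.get("condition", pd.Series(["normal"]))[0])
        ),
        bend_id=int(sidecar.get("bend_id", 0)),
        ground_truth=events,
        meta=sidecar.get("meta", {}),
    )


def trial_paths(trials_dir: Path) -> List[Path]:
    return sorted(Path(trials_dir).glob("trial_*.csv"))


def write_segments(path: Path, segments: pd.DataFrame, cfg_hash: str = "") -> Path:
    """Write the segments table as TSV with a provenance comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(provenance_line(cfg_hash))
        segments.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT,
                        lineterminator="\n")
    return path


def read_segments(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: Path, files: Sequence[Path], cfg_hash: str, seed: Optional[int],
    extra: Optional[Dict] = None,
) -> Path:
    """Checksum manifest of every produced file."""
    manifest = {
        "version": __version__,
        "config": cfg_hash,
        "seed": seed,
        "files": {Path(p).name: sha256_file(p) for p in sorted(map(str, files))},
    }
    if extra:
        manifest.update(extra)
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def write_json(path: Path, payload: Dict, cfg_hash: str = "") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"version": __version__, "config": cfg_hash, **payload}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path
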