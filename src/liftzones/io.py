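"""On-disk layout of a simulated experiment.

A dataset directory holds one sub-directory per trial with the five
segment CSV files (and their sidecar JSONs), plus:

* ``manifest.yaml`` -- every parameter and seed of the run;
* ``subjects.json`` -- anthropometry (true and measured lengths);
* ``truth.csv``     -- per-trial ground-truth V, H, zone, group.

All files are plain text so a dataset is diffable and versionable.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .anthropometry import SEGMENTS, SegmentLengths
from .sensor_fusion import ImuStream, read_imu_csv, write_imu_csv
from .synthetic import Experiment, SyntheticSubject
from .zoning import group_from_zone

__all__ = ["write_experiment", "read_trial_streams", "read_truth", "read_subjects"]


def _trial_dirname(subject_id: str, zone: int, rep: int) -> str:
    return f"{subject_id}_z{zone:02d}_r{rep}"


def write_experiment(experiment: Experiment, out_dir: str | Path) -> Path:
    """Write a full experiment dataset; returns the dataset root."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.yaml").write_text(yaml.safe_dump(experiment.manifest, sort_keys=True))

    subjects = {
        s.id: {
            "stature": s.stature,
            "sex": s.sex,
            "true_lengths": s.true_lengths.as_dict(),
            "measured_lengths": s.measured_lengths.as_dict(),
            "forearm_measured": s.forearm_measured,
        }
        for s in experiment.subjects
    }
    (out / "subjects.json").write_text(json.dumps(subjects, indent=1))

    rows = []
    for trial in experiment.trials:
        spec = trial.spec
        name = _trial_dirname(spec.subject_id, spec.zone, spec.repetition)
        tdir = out / "trials" / name
        tdir.mkdir(parents=True, exist_ok=True)
        for segment, stream in trial.streams.items():
            write_imu_csv(stream, tdir / f"{segment}.csv")
        rows.append(
            {
                "trial": name,
                "subject": spec.subject_id,
                "zone": spec.zone,
                "repetition": spec.repetition,
                "seed": spec.seed,
                "true_v": trial.truth.v,
                "true_h": trial.truth.h,
                "true_zone": trial.true_zone.index,
                "true_group": group_from_zone(trial.true_zone),
            }
        )
    pd.DataFrame(rows).sort_values("trial").to_csv(out / "truth.csv", index=False,
                                                   float_format="%.9g")
    return out


def read_truth(dataset: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(dataset) / "truth.csv")


def read_subjects(dataset: str | Path) -> dict[str, SyntheticSubject]:
    """Rehydrate the cohort from ``subjects.json``."""
    raw = json.loads((Path(dataset) / "subjects.json").read_text())
    out = {}
    for sid, d in raw.items():
        out[sid] = SyntheticSubject(
            id=sid,
            stature=d["stature"],
            sex=d["sex"],
            true_lengths=SegmentLengths(**d["true_lengths"]),
            measured_lengths=SegmentLengths(**d["measured_lengths"]),
            forearm_measured=d["forearm_measured"],
        )
    return out


def read_trial_streams(trial_dir: str | Path) -> dict[str, ImuStream]:
    """Read the five segment streams of one trial directory."""
    trial_dir = Path(trial_dir)
    streams = {}
    for segment in SEGMENTS:
        path = trial_dir / f"{segment}.csv"
        if path.exists():
            streams[segment] = read_imu_csv(path, segment=segment)
    if not streams:
        raise FileNotFoundError(f"no segment CSV files in {trial_dir}")
    return streams
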