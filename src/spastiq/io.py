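"""Session storage, cohort layout and configuration.

A cohort directory contains one sub-directory per subject:

    cohort/
      S000/
        manifest.json          # subject_id, mas_grade, muscle, trials, provenance
        emg_t000.csv           # columns: time_s, emg_mV
        gyro_t000.csv          # columns: time_s, gx, gy, gz  (deg/s)
        ...

Plain CSV is used for language neutrality and inspectability.  Malformed
trials (missing files, non-monotone time stamps) are skipped with a logged
reason; a missing manifest or a unit/column mismatch is an error.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .preprocess import RawTrial
from .synthetic import SimulatedSubject

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "write_session",
    "read_session",
    "write_cohort",
    "read_cohort",
]

EMG_COLUMNS = ["time_s", "emg_mV"]
GYRO_COLUMNS = ["time_s", "gx", "gy", "gz"]

#: Every numeric default of the pipeline, overridable from a single YAML
#: file with the same block structure.
DEFAULT_CONFIG: dict = {
    "simulate": {
        "n_subjects": 24,
        "grade_distribution": None,  # None -> reference 24-subject tally, scaled
        "seed": 0,
        "trials_range": [15, 20],
        "dsrt_noise_sd": 3.0,
    },
    "preprocess": {
        "baseline_window": 0.5,
        "k": 3.0,
        "min_run": 0.025,
        "rms_window": 0.05,
        "clip_value": 4.0,
        "clip_fraction_max": 0.05,
        "emg_baseline_sd_max": 0.5,
        "duration_range": [0.3, 10.0],
    },
    "lambda": {
        "majority_threshold": 0.5,
        "min_points": 3,
        "confidence": 0.95,
    },
    "kinematic": {
        "acc1": 4000.0,
        "duration_range": [1.0, 2.0],
    },
    "svr": {
        "penalty_c": 30.0,
        "epsilon": 0.09,
        "sigma": 0.007,
        "kernel_form": "gamma",
        "standardize_features": True,
    },
    "evaluate": {
        "methods": ["lambda", "kinematic", "fusion"],
    },
}


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config merged over the package defaults."""
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return _merge(cfg, user)


def write_session(
    directory: str | Path,
    trials: Iterable[RawTrial],
    mas_grade: str,
    provenance: Mapping | str = "recorded",
) -> Path:
    """Write one subject's session in the documented layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    trials = list(trials)
    if not trials:
        raise ValueError("cannot write an empty session")
    subject_id = trials[0].subject_id
    manifest: dict = {
        "subject_id": subject_id,
        "mas_grade": mas_grade,
        "muscle": trials[0].muscle,
        "trials": {},
        "provenance": provenance if isinstance(provenance, str) else dict(provenance),
    }
    for t in trials:
        emg_name = f"emg_{t.trial_id}.csv"
        gyro_name = f"gyro_{t.trial_id}.csv"
        pd.DataFrame(
            {"time_s": np.arange(len(t.emg)) / t.fs_emg, "emg_mV": t.emg}
        ).to_csv(directory / emg_name, index=False)
        pd.DataFrame(
            {
                "time_s": np.arange(len(t.gyro)) / t.fs_gyro,
                "gx": t.gyro[:, 0],
                "gy": t.gyro[:, 1],
                "gz": t.gyro[:, 2],
            }
        ).to_csv(directory / gyro_name, index=False)
        manifest["trials"][t.trial_id] = {
            "emg": emg_name,
            "gyro": gyro_name,
            "fs_emg": t.fs_emg,
            "fs_gyro": t.fs_gyro,
        }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return directory


def read_session(directory: str | Path) -> tuple[dict, list[RawTrial]]:
    """Read one subject directory; returns (manifest, trials).

    Trials with non-monotone time stamps are skipped with reason
    ``bad_timebase``; a file referenced by the manifest but absent on disk
    is an error naming the file, as is a column/unit mismatch.
    """
    directory = Path(directory)
    mpath = directory / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"missing manifest: {mpath}")
    with open(mpath) as fh:
        manifest = json.load(fh)

    trials: list[RawTrial] = []
    skipped = 0
    for trial_id, entry in manifest["trials"].items():
        frames = {}
        for key, columns in (("emg", EMG_COLUMNS), ("gyro", GYRO_COLUMNS)):
            fpath = directory / entry[key]
            if not fpath.exists():
                raise FileNotFoundError(f"manifest references missing file: {fpath}")
            df = pd.read_csv(fpath, float_precision="round_trip")
            if list(df.columns) != columns:
                raise ValueError(
                    f"{fpath}: expected columns {columns} (declared units), got {list(df.columns)}"
                )
            frames[key] = df
        if any(np.any(np.diff(frames[k]["time_s"].to_numpy()) <= 0) for k in frames):
            logger.warning("trial %s skipped: bad_timebase", trial_id)
            skipped += 1
            continue
        trials.append(
            RawTrial(
                emg=frames["emg"]["emg_mV"].to_numpy(),
                gyro=frames["gyro"][["gx", "gy", "gz"]].to_numpy(),
                subject_id=manifest["subject_id"],
                trial_id=trial_id,
                muscle=manifest.get("muscle", "BB"),
                fs_emg=float(entry.get("fs_emg", 1000.0)),
                fs_gyro=float(entry.get("fs_gyro", 100.0)),
            )
        )
    if skipped:
        logger.info("session %s: skipped %d malformed trial(s)", manifest["subject_id"], skipped)
    return manifest, trials


def write_cohort(directory: str | Path, cohort: Iterable[SimulatedSubject],
                 master_seed: int | None = None) -> Path:
    """Write a simulated cohort, one subject directory each."""
    directory = Path(directory)
    for subject in cohort:
        prov = {
            "simulated": True,
            "master_seed": master_seed,
            "tsrt_true": subject.params.tsrt_true,
            "dsrt_slope": subject.params.dsrt_slope,
            "perturb_gain": subject.params.perturb_gain,
        }
        write_session(
            directory / subject.params.subject_id,
            subject.trials,
            mas_grade=subject.params.mas_grade,
            provenance=prov,
        )
    return directory


def read_cohort(directory: str | Path) -> list[tuple[dict, list[RawTrial]]]:
    """Read every subject directory (those containing a manifest) in order."""
    directory = Path(directory)
    sessions = []
    for sub in sorted(p for p in directory.iterdir() if (p / "manifest.json").exists()):
        sessions.append(read_session(sub))
    if not sessions:
        raise FileNotFoundError(f"no subject sessions found under {directory}")
    return sessions
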