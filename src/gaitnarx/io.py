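"""Plain-text trial, session and artifact formats.

A raw trial is a CSV (``time_s, emg_ta, emg_gm, angle_deg, moment_nmkg``)
plus a JSON sidecar (``<id>.events.json``) holding events, condition and
sample rates; raw-rate EMG, when present, lives in ``<id>.raw.csv``.  A
session is a directory of trials listed in ``manifest.json`` together with
generator provenance.  Processed trials use the same CSV layout with an
``events`` sidecar keyed by sample index.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .trials import FS, FS_RAW, GaitEvent, ProcessedTrial, RawTrial

SCHEMA_VERSION = 1
_COLUMNS = ["time_s", "emg_ta", "emg_gm", "angle_deg", "moment_nmkg"]
_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def config_hash(obj) -> str:
    """Stable SHA-256 of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix("").with_suffix(".events.json")


def write_trial(trial: RawTrial, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / f"{trial.trial_id}.csv"
    n = trial.n_samples
    frame = pd.DataFrame(
        {
            "time_s": np.arange(n) / trial.fs,
            "emg_ta": trial.emg_envelope[:, 0],
            "emg_gm": trial.emg_envelope[:, 1],
            "angle_deg": trial.angle,
            "moment_nmkg": trial.moment,
        }
    )
    frame.to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "trial_id": trial.trial_id,
        "condition": trial.condition,
        "fs": trial.fs,
        "fs_raw": trial.fs_raw,
        "events": [{"name": e.name, "time_s": e.time_s} for e in trial.events],
        "has_raw_emg": trial.emg_raw is not None,
    }
    _sidecar_path(csv_path).write_text(json.dumps(sidecar, indent=1))
    if trial.emg_raw is not None:
        raw_frame = pd.DataFrame(trial.emg_raw, columns=["emg_ta_raw", "emg_gm_raw"])
        raw_frame.to_csv(
            csv_path.with_suffix("").with_suffix(".raw.csv"),
            index=False,
            float_format=_FLOAT_FMT,
        )
    return csv_path


def read_trial(csv_path) -> RawTrial:
    csv_path = Path(csv_path)
    sidecar_path = _sidecar_path(csv_path)
    if not sidecar_path.exists():
        raise DataError(f"missing events sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    frame = pd.read_csv(csv_path)
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"{csv_path}: missing columns {missing}")
    if frame[_COLUMNS].isna().any().any():
        bad = int(frame[_COLUMNS].isna().any(axis=1).idxmax())
        raise DataError(f"{csv_path}: NaN sample at row {bad}")
    emg_raw = None
    if sidecar.get("has_raw_emg"):
        raw_path = csv_path.with_suffix("").with_suffix(".raw.csv")
        if not raw_path.exists():
            raise DataError(f"missing raw EMG file {raw_path}")
        emg_raw = pd.read_csv(raw_path).to_numpy(dtype=float)
    return RawTrial(
        trial_id=sidecar["trial_id"],
        condition=sidecar["condition"],
        emg_envelope=frame[["emg_ta", "emg_gm"]].to_numpy(dtype=float),
        angle=frame["angle_deg"].to_numpy(dtype=float),
        moment=frame["moment_nmkg"].to_numpy(dtype=float),
        events=tuple(
            GaitEvent(name=e["name"], time_s=float(e["time_s"]))
            for e in sidecar["events"]
        ),
        emg_raw=emg_raw,
        fs=float(sidecar.get("fs", FS)),
        fs_raw=float(sidecar.get("fs_raw", FS_RAW)),
    )


def write_session(trials, directory, provenance: dict | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    seen = set()
    for trial in trials:
        if trial.trial_id in seen:
            raise DataError(f"duplicate trial_id {trial.trial_id!r}")
        seen.add(trial.trial_id)
        path = write_trial(trial, directory)
        entries.append(
            {
                "path": path.name,
                "trial_id": trial.trial_id,
                "condition": trial.condition,
            }
        )
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "fs": FS,
        "fs_raw": FS_RAW,
        "trials": entries,
        "provenance": provenance or {},
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_session(directory) -> tuple[list[RawTrial], dict]:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise DataError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    trials = [read_trial(directory / e["path"]) for e in manifest["trials"]]
    return trials, manifest


# --- processed trials -------------------------------------------------------


def write_processed(trial: ProcessedTrial, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / f"{trial.trial_id}.csv"
    frame = pd.DataFrame(
        {
            "time_s": np.arange(trial.n_samples) * trial.dt,
            "emg_ta": trial.x[:, 0],
            "emg_gm": trial.x[:, 1],
            "angle_deg": trial.y[:, 0],
            "moment_nmkg": trial.y[:, 1],
        }
    )
    frame.to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "trial_id": trial.trial_id,
        "condition": trial.condition,
        "dt": trial.dt,
        "events": [{"name": n, "sample": int(i)} for n, i in trial.events],
        "processed": True,
    }
    _sidecar_path(csv_path).write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_processed(csv_path) -> ProcessedTrial:
    csv_path = Path(csv_path)
    sidecar_path = _sidecar_path(csv_path)
    if not sidecar_path.exists():
        raise DataError(f"missing events sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    frame = pd.read_csv(csv_path)
    if frame[_COLUMNS].isna().any().any():
        bad = int(frame[_COLUMNS].isna().any(axis=1).idxmax())
        raise DataError(f"{csv_path}: NaN sample at row {bad}")
    return ProcessedTrial(
        trial_id=sidecar["trial_id"],
        condition=sidecar["condition"],
        x=frame[["emg_ta", "emg_gm"]].to_numpy(dtype=float),
        y=frame[["angle_deg", "moment_nmkg"]].to_numpy(dtype=float),
        events=tuple((e["name"], int(e["sample"])) for e in sidecar["events"]),
        dt=float(sidecar.get("dt", 1.0 / FS)),
    )


def write_processed_session(trials, directory, provenance: dict | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for trial in trials:
        path = write_processed(trial, directory)
        entries.append(
            {"path": path.name, "trial_id": trial.trial_id, "condition": trial.condition}
        )
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "processed": True,
        "trials": entries,
        "provenance": provenance or {},
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_processed_session(directory) -> tuple[list[ProcessedTrial], dict]:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise DataError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    trials = [read_processed(directory / e["path"]) for e in manifest["trials"]]
    return trials, manifest
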