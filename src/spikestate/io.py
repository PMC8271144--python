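"""Reading and writing sessions and result tables.

A session lives in one directory:

* ``manifest.yaml`` -- session id/type, unit list with per-unit recording
  windows, waveform sampling rate, relative file paths.
* ``spikes.csv`` -- two columns ``unit_id,time_s``, one row per spike.
* ``epochs.csv`` -- ``label,start_s,stop_s``.
* ``waveforms/<unit_id>.csv`` -- one snippet matrix per unit (rows = spikes).
* ``ground_truth.json`` -- planted parameters, synthetic sessions only.

Everything is plain text and round-trips to full float precision (floats are
serialized with :func:`repr`, which is exact for IEEE doubles).
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    BehaviorEpoch,
    GroundTruth,
    SessionRecord,
    SpikeTrain,
    ValidationError,
    WaveformSet,
)

MANIFEST_NAME = "manifest.yaml"


class SessionLoadError(IOError):
    """A session directory is missing a required file or is malformed."""


def _fmt(x: float) -> str:
    return repr(float(x))


def write_session(
    session: SessionRecord, path: str | os.PathLike, ground_truth: GroundTruth | None = None
) -> None:
    """Write ``session`` to directory ``path`` (created if needed)."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    with open(root / "spikes.csv", "w") as fh:
        fh.write("unit_id,time_s\n")
        for train in session.spike_trains:
            for t in train.spike_times:
                fh.write(f"{train.unit_id},{_fmt(t)}\n")

    with open(root / "epochs.csv", "w") as fh:
        fh.write("label,start_s,stop_s\n")
        for ep in session.epochs:
            fh.write(f"{ep.label},{_fmt(ep.start)},{_fmt(ep.stop)}\n")

    wf_rate = None
    if session.waveform_sets:
        wf_dir = root / "waveforms"
        wf_dir.mkdir(exist_ok=True)
        rates = {ws.sampling_rate for ws in session.waveform_sets.values()}
        if len(rates) > 1:
            raise ValidationError("waveform sets disagree on sampling rate")
        wf_rate = rates.pop()
        for uid, ws in sorted(session.waveform_sets.items()):
            with open(wf_dir / f"{uid}.csv", "w") as fh:
                for row in ws.waveforms:
                    fh.write(",".join(_fmt(x) for x in row) + "\n")

    manifest = {
        "session_id": session.session_id,
        "type": session.session_type,
        "sampling_rate": wf_rate,
        "units": [
            {
                "unit_id": t.unit_id,
                "t_start": float(t.t_start),
                "t_stop": float(t.t_stop),
                "has_waveforms": t.unit_id in session.waveform_sets,
            }
            for t in session.spike_trains
        ],
        "files": {"spikes": "spikes.csv", "epochs": "epochs.csv", "waveforms": "waveforms"},
    }
    with open(root / MANIFEST_NAME, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)

    if ground_truth is not None:
        payload = {
            "true_class": ground_truth.true_class,
            "true_width": ground_truth.true_width,
            "planted_dimensionality": ground_truth.planted_dimensionality,
            "planted_bc_sign": ground_truth.planted_bc_sign,
            "planted_balance_coupling": ground_truth.planted_balance_coupling,
        }
        with open(root / "ground_truth.json", "w") as fh:
            json.dump(payload, fh, indent=1)


def read_session(path: str | os.PathLike) -> SessionRecord:
    """Load and validate the session stored in directory ``path``."""
    root = Path(path)
    manifest_path = root / MANIFEST_NAME
    if not manifest_path.exists():
        raise SessionLoadError(f"no {MANIFEST_NAME} in {root}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)

    files = manifest.get("files", {})
    spikes_path = root / files.get("spikes", "spikes.csv")
    epochs_path = root / files.get("epochs", "epochs.csv")
    for p in (spikes_path, epochs_path):
        if not p.exists():
            raise SessionLoadError(f"missing session file {p}")

    spikes = pd.read_csv(spikes_path, dtype={"unit_id": str, "time_s": float})
    by_unit = {uid: g["time_s"].to_numpy() for uid, g in spikes.groupby("unit_id")}

    trains = []
    for entry in manifest["units"]:
        uid = str(entry["unit_id"])
        times = by_unit.pop(uid, np.empty(0))
        trains.append(
            SpikeTrain(uid, times, float(entry["t_start"]), float(entry["t_stop"]))
        )
    if by_unit:
        raise SessionLoadError(
            f"spikes.csv contains units absent from the manifest: {sorted(by_unit)}"
        )

    epochs_df = pd.read_csv(epochs_path, dtype={"label": str})
    epochs = [
        BehaviorEpoch(str(r.label), float(r.start_s), float(r.stop_s))
        for r in epochs_df.itertuples()
    ]

    waveform_sets: dict[str, WaveformSet] = {}
    wf_dir = root / files.get("waveforms", "waveforms")
    rate = manifest.get("sampling_rate")
    for entry in manifest["units"]:
        if entry.get("has_waveforms"):
            uid = str(entry["unit_id"])
            wf_path = wf_dir / f"{uid}.csv"
            if not wf_path.exists():
                raise SessionLoadError(f"missing waveform file {wf_path}")
            mat = np.loadtxt(wf_path, delimiter=",", ndmin=2)
            waveform_sets[uid] = WaveformSet(uid, mat, float(rate))

    return SessionRecord(
        session_id=str(manifest["session_id"]),
        session_type=str(manifest["type"]),
        spike_trains=trains,
        waveform_sets=waveform_sets,
        epochs=epochs,
    )


def read_ground_truth(path: str | os.PathLike) -> GroundTruth:
    """Load ``ground_truth.json`` from a synthetic session directory."""
    with open(Path(path) / "ground_truth.json") as fh:
        payload = json.load(fh)
    return GroundTruth(
        true_class={str(k): str(v) for k, v in payload["true_class"].items()},
        true_width={str(k): float(v) for k, v in payload["true_width"].items()},
        planted_dimensionality=int(payload["planted_dimensionality"]),
        planted_bc_sign={str(k): int(v) for k, v in payload["planted_bc_sign"].items()},
        planted_balance_coupling=float(payload["planted_balance_coupling"]),
    )


def write_results_table(rows, path: str | os.PathLike, columns=None) -> None:
    """Write a sequence of homogeneous mapping records as a headed CSV.

    Column order follows the first record (or explicit ``columns``); NaN
    serializes as an empty field. An empty record sequence yields a
    header-only CSV and requires ``columns`` (or a DataFrame) to supply the
    schema.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if not rows:
            if columns is None:
                raise ValueError("cannot infer a column schema from zero records")
            df = pd.DataFrame(columns=list(columns))
        else:
            schema = list(columns) if columns is not None else list(rows[0])
            for r in rows:
                if list(r) != schema:
                    raise ValueError("heterogeneous record schema")
            df = pd.DataFrame(rows, columns=schema)
    df.to_csv(path, index=False)
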