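"""CSV/JSON interchange formats and run manifests.

All tables are comma-separated UTF-8 with a mandatory header row; times are
seconds printed with six decimals.  Spike tables carry (unit_id, time_s);
stimulation tables (onset_s, pulse_ms, intensity_mA, condition); segment
tables one row per syllable rendition.  Manifests record the configuration
snapshot, input checksums, package version and seed so that identical
manifests reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ephys import SpikeTrain, StimulationProtocol

SPIKE_COLUMNS = ["unit_id", "time_s"]
STIM_COLUMNS = ["onset_s", "pulse_ms", "intensity_mA", "condition"]
SEGMENT_COLUMNS = [
    "bird",
    "day_dph",
    "rendition",
    "syllable_index",
    "type",
    "onset_s",
    "offset_s",
    "duration_ms",
    "rel_amplitude",
    "f0_hz",
    "harmonicity",
]
FLOAT_FMT = "%.6f"


def _require_columns(frame: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


def write_spike_trains(path: str | Path, trains: list[SpikeTrain]) -> None:
    rows = [
        {"unit_id": t.unit_id, "time_s": s} for t in trains for s in t.spike_times
    ]
    pd.DataFrame(rows, columns=SPIKE_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_spike_trains(
    path: str | Path, session_duration: float | None = None
) -> list[SpikeTrain]:
    frame = pd.read_csv(path)
    _require_columns(frame, SPIKE_COLUMNS, path)
    times = pd.to_numeric(frame["time_s"], errors="coerce")
    if times.isna().any():
        raise ValueError(f"{path}: non-numeric spike times")
    if (times < 0).any():
        raise ValueError(f"{path}: negative spike times")
    frame = frame.assign(time_s=times)
    trains = []
    for unit_id, g in frame.groupby("unit_id", sort=True):
        t = g["time_s"].to_numpy()
        if np.any(np.diff(t) < 0):
            warnings.warn(f"{path}: spike times for {unit_id} unsorted; sorting")
            t = np.sort(t)
        duration = session_duration if session_duration is not None else (
            float(t[-1]) if len(t) else 0.0
        )
        trains.append(
            SpikeTrain(unit_id=str(unit_id), spike_times=t, session_duration=duration)
        )
    return trains


def write_stimulations(path: str | Path, protocol: StimulationProtocol) -> None:
    pd.DataFrame(
        {
            "onset_s": protocol.onsets,
            "pulse_ms": protocol.pulse_duration_ms,
            "intensity_mA": protocol.intensity_ma,
            "condition": protocol.condition,
        }
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_stimulations(path: str | Path) -> list[StimulationProtocol]:
    """Read stimulation events; one protocol per condition label in the file."""
    frame = pd.read_csv(path)
    _require_columns(frame, STIM_COLUMNS, path)
    onsets = pd.to_numeric(frame["onset_s"], errors="coerce")
    if onsets.isna().any():
        raise ValueError(f"{path}: non-numeric stimulation onsets")
    if (onsets < 0).any():
        raise ValueError(f"{path}: negative stimulation onsets")
    frame = frame.assign(onset_s=onsets)
    protocols = []
    for cond, g in frame.groupby("condition", sort=False):
        t = g["onset_s"].to_numpy()
        if np.any(np.diff(t) < 0):
            warnings.warn(f"{path}: onsets for {cond} unsorted; sorting")
            t = np.sort(t)
        isi = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
        protocols.append(
            StimulationProtocol(
                onsets=t,
                pulse_duration_ms=float(g["pulse_ms"].iloc[0]),
                inter_stim_interval=isi,
                intensity_ma=float(g["intensity_mA"].iloc[0]),
                condition=str(cond),
            )
        )
    return protocols


def write_segments(path: str | Path, segments: pd.DataFrame) -> None:
    _require_columns(segments, SEGMENT_COLUMNS, path)
    segments[SEGMENT_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FMT)


def read_segments(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(frame, SEGMENT_COLUMNS, path)
    return frame


def write_ground_truth(path: str | Path, truth) -> None:
    """Serialize a RenditionTruth (or list of them) to JSON."""
    def encode(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        raise TypeError(f"cannot serialize {type(obj)}")

    Path(path).write_text(json.dumps(truth, default=encode, indent=1))


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: dict,
    seed: int,
    inputs: list[str | Path] = (),
    outputs: list[str | Path] = (),
) -> dict:
    """Write the run manifest (config snapshot, checksums, version, inventory)."""
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {str(p): sha256_of(p) for p in inputs},
        "outputs": {str(p): sha256_of(p) for p in outputs},
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
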