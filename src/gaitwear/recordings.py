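"""Data model and I/O for multi-sensor daily-life recording sessions.

A session bundles the synchronized streams of up to five body-worn IMUs
(chest, both wrists, both ankles), each carrying tri-axial acceleration
(m/s^2), tri-axial angular rate (deg/s) and barometric altitude (m, 10 cm
device resolution), sampled at 50 Hz, together with a per-sample activity
label track and per-subject clinical metadata.

On disk a session is a directory of plain-text files: one
``<location>.csv`` per sensor, a ``labels.csv``, and a ``meta.yaml`` --
chosen over a single wide table so partial sensor setups stay natural.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: Canonical sensor ordering; fixes feature-vector column order everywhere.
LOCATIONS = ("chest", "wrist_left", "wrist_right", "ankle_left", "ankle_right")

ACTIVITY_CLASSES = ("lying", "sitting", "standing", "walking", "stairs")
TRANSITION_CLASSES = ("trans_lying_sit", "trans_sit_stand", "trans_stand_walk")
LABEL_VOCABULARY = ACTIVITY_CLASSES + TRANSITION_CLASSES

#: Adjoining activity classes of each transition label (directionless).
TRANSITION_PAIRS = {
    "trans_lying_sit": ("lying", "sitting"),
    "trans_sit_stand": ("sitting", "standing"),
    "trans_stand_walk": ("standing", "walking"),
}

DEFAULT_SAMPLE_RATE_HZ = 50.0
BARO_RESOLUTION_M = 0.1

_SENSOR_COLUMNS = ["time_s", "acc_x", "acc_y", "acc_z",
                   "gyro_x", "gyro_y", "gyro_z", "baro_m"]


class SessionError(ValueError):
    """Raised for malformed, incomplete, or desynchronized sessions."""


@dataclasses.dataclass
class SensorStream:
    """One sensor location's synchronized channels.

    accel is in m/s^2 (gravity magnitude 9.81), gyro in deg/s, baro_alt in
    meters relative to an arbitrary reference level.
    """

    location: str
    accel: np.ndarray
    gyro: np.ndarray
    baro_alt: np.ndarray
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise SessionError(f"unknown sensor location {self.location!r}")
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.baro_alt = np.asarray(self.baro_alt, dtype=float).reshape(-1)
        n = len(self.accel)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise SessionError("accel must be N x 3")
        if self.gyro.shape != (n, 3):
            raise SessionError("desynchronized session: gyro length mismatch")
        if self.baro_alt.shape != (n,):
            raise SessionError("desynchronized session: baro length mismatch")
        if not self.sample_rate_hz > 0:
            raise SessionError("sample_rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.accel)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SensorStream):
            return NotImplemented
        return (self.location == other.location
                and self.sample_rate_hz == other.sample_rate_hz
                and np.array_equal(self.accel, other.accel)
                and np.array_equal(self.gyro, other.gyro)
                and np.array_equal(self.baro_alt, other.baro_alt))


@dataclasses.dataclass
class LabelTrack:
    """Per-sample ground-truth labels over the 8-class vocabulary."""

    labels: np.ndarray
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = [(i, lab) for i, lab in enumerate(self.labels)
               if lab not in LABEL_VOCABULARY]
        if bad:
            i, lab = bad[0]
            raise SessionError(
                f"label vocabulary violation: unknown label {lab!r} at row {i}")
        if not self.sample_rate_hz > 0:
            raise SessionError("sample_rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelTrack):
            return NotImplemented
        return (self.sample_rate_hz == other.sample_rate_hz
                and np.array_equal(self.labels, other.labels))


@dataclasses.dataclass
class RecordingSession:
    """One subject's synchronized streams + label track + metadata."""

    subject_id: str
    affected_side: str
    streams: dict
    label_track: LabelTrack
    clinical: dict | None = None

    def __post_init__(self) -> None:
        if self.affected_side not in ("left", "right"):
            raise SessionError("affected_side must be 'left' or 'right'")
        lengths = {loc: len(s) for loc, s in self.streams.items()}
        if len(set(lengths.values())) > 1:
            raise SessionError(f"desynchronized session: stream lengths {lengths}")
        if self.streams and len(self.label_track) != next(iter(lengths.values())):
            raise SessionError(
                "desynchronized session: label track length "
                f"{len(self.label_track)} != stream length {next(iter(lengths.values()))}")

    @property
    def n_samples(self) -> int:
        return len(self.label_track)

    @property
    def sample_rate_hz(self) -> float:
        return self.label_track.sample_rate_hz


# ---------------------------------------------------------------------------
# Sensor configurations A-E

#: A: all sensors; B: no chest; C: wrist+ankle contralateral to the affected
#: side; D: wrist+ankle on the affected side; E: both wrists.
CONFIGURATION_IDS = ("A", "B", "C", "D", "E")

CONFIGURATION_SIZES = {"A": 5, "B": 4, "C": 2, "D": 2, "E": 2}


def resolve_locations(config_id: str, affected_side: str | None = None) -> list[str]:
    """Ordered sensor locations of a configuration (canonical order)."""
    if config_id == "A":
        return list(LOCATIONS)
    if config_id == "B":
        return [loc for loc in LOCATIONS if loc != "chest"]
    if config_id == "E":
        return ["wrist_left", "wrist_right"]
    if config_id in ("C", "D"):
        if affected_side not in ("left", "right"):
            raise SessionError(
                f"configuration {config_id} requires a known affected side")
        if config_id == "C":  # non-affected (contralateral) side
            side = "right" if affected_side == "left" else "left"
        else:  # D: affected (ipsilateral) side
            side = affected_side
        return [f"wrist_{side}", f"ankle_{side}"]
    raise SessionError(f"unknown sensor configuration {config_id!r}")


def select_configuration(session: RecordingSession, config_id: str) -> list[SensorStream]:
    """Streams of ``session`` required by ``config_id``, canonical order."""
    locations = resolve_locations(config_id, session.affected_side)
    missing = [loc for loc in locations if loc not in session.streams]
    if missing:
        raise SessionError(
            f"configuration unavailable for session {session.subject_id!r}: "
            f"missing {missing}")
    return [session.streams[loc] for loc in locations]


# ---------------------------------------------------------------------------
# Label resampling (video frame rate -> IMU rate)

def resample_labels(video_labels: Sequence[str], source_rate_hz: float,
                    target_rate_hz: float) -> LabelTrack:
    """Nearest-neighbor resampling of a per-frame label sequence.

    Output sample i (time i/target) takes the label of the nearest source
    frame (time j/source); exact ties go to the earlier frame. Nearest-
    neighbor (rather than majority over frame spans) preserves the short
    transition labels.
    """
    if len(video_labels) == 0:
        raise SessionError("empty label sequence")
    if not (source_rate_hz > 0 and target_rate_hz > 0):
        raise SessionError("rates must be positive")
    n_in = len(video_labels)
    n_out = int(round(n_in * target_rate_hz / source_rate_hz))
    i = np.arange(n_out)
    x = i * (source_rate_hz / target_rate_hz)
    j = np.ceil(x - 0.5).astype(int)  # ties toward the earlier frame
    j = np.clip(j, 0, n_in - 1)
    labels = np.asarray(video_labels, dtype=object)[j]
    return LabelTrack(labels=labels, sample_rate_hz=target_rate_hz)


# ---------------------------------------------------------------------------
# Disk format

def write_session(session: RecordingSession, path: str | Path) -> Path:
    """Write a session directory (per-location CSVs, labels.csv, meta.yaml)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    fs = session.sample_rate_hz
    for loc, stream in session.streams.items():
        t = np.arange(len(stream)) / fs
        df = pd.DataFrame(
            np.column_stack([t, stream.accel, stream.gyro, stream.baro_alt]),
            columns=_SENSOR_COLUMNS)
        df.to_csv(path / f"{loc}.csv", index=False, float_format="%.17g")
    t = np.arange(session.n_samples) / fs
    pd.DataFrame({"time_s": t, "label": session.label_track.labels}).to_csv(
        path / "labels.csv", index=False, float_format="%.17g")
    meta = {
        "subject_id": session.subject_id,
        "affected_side": session.affected_side,
        "sample_rate_hz": float(fs),
        "locations": sorted(session.streams),
    }
    if session.clinical is not None:
        meta["clinical"] = {k: float(v) for k, v in session.clinical.items()}
    with open(path / "meta.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return path


def read_session(path: str | Path) -> RecordingSession:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    meta_path = path / "meta.yaml"
    if not meta_path.exists():
        raise SessionError(f"incomplete session: missing meta.yaml in {path}")
    with open(meta_path, encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    fs = float(meta["sample_rate_hz"])
    streams: dict[str, SensorStream] = {}
    for loc in meta.get("locations", []):
        csv_path = path / f"{loc}.csv"
        if not csv_path.exists():
            raise SessionError(f"incomplete session: missing {loc}.csv")
        df = pd.read_csv(csv_path, float_precision="round_trip")
        if list(df.columns) != _SENSOR_COLUMNS:
            raise SessionError(f"malformed sensor file {csv_path}")
        streams[loc] = SensorStream(
            location=loc,
            accel=df[["acc_x", "acc_y", "acc_z"]].to_numpy(),
            gyro=df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(),
            baro_alt=df["baro_m"].to_numpy(),
            sample_rate_hz=fs)
    labels_path = path / "labels.csv"
    if not labels_path.exists():
        raise SessionError("incomplete session: missing labels.csv")
    labels_df = pd.read_csv(labels_path)
    track = LabelTrack(labels=labels_df["label"].to_numpy(dtype=object),
                       sample_rate_hz=fs)
    clinical = meta.get("clinical")
    return RecordingSession(
        subject_id=str(meta["subject_id"]),
        affected_side=meta["affected_side"],
        streams=streams,
        label_track=track,
        clinical=dict(clinical) if clinical else None)
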