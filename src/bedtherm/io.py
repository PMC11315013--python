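"""Serialization of recordings, feature tables and run configuration.

Streams travel as a single long-format CSV per session (columns
``channel, t_seconds, value_c``; Parquet with the same schema optional) next
to a YAML manifest holding subject/session ids, setting, lights-off,
presence intervals and the stream file path.  Timestamps are seconds from
session start.  Temperatures serialize with full precision (repr), never
locale-dependent.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .simulate import (ArtifactSpec, CHANNEL_SPECS, PhysioParams, RawStream,
                       SessionRecording, StudyFixture, Participant)

__all__ = [
    "SchemaError", "UnknownChannelError", "NonMonotoneTimestampError",
    "MissingFileError", "write_session", "load_session", "write_study",
    "load_study", "write_feature_table", "read_feature_table", "RunConfig",
]


class SchemaError(ValueError):
    """A stream or manifest violates the on-disk schema."""


class UnknownChannelError(SchemaError):
    pass


class NonMonotoneTimestampError(SchemaError):
    pass


class MissingFileError(FileNotFoundError):
    pass


def _streams_frame(rec: SessionRecording) -> pd.DataFrame:
    parts = []
    for channel in sorted(rec.streams):
        s = rec.streams[channel]
        parts.append(pd.DataFrame({"channel": channel,
                                   "t_seconds": s.timestamps,
                                   "value_c": s.values}))
    return pd.concat(parts, ignore_index=True)


def write_session(rec: SessionRecording, directory, fmt: str = "csv") -> pathlib.Path:
    """Write one session (streams + manifest); returns the manifest path."""
    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    frame = _streams_frame(rec)
    if fmt == "parquet":
        stream_file = f"{rec.session_id}_streams.parquet"
        frame.to_parquet(d / stream_file, index=False)
    elif fmt == "csv":
        stream_file = f"{rec.session_id}_streams.csv"
        frame.to_csv(d / stream_file, index=False, float_format="%.10g")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    manifest = {
        "subject_id": rec.subject_id,
        "session_id": rec.session_id,
        "setting": rec.setting,
        "duration_minutes": float(rec.duration_minutes),
        "lights_off": None if rec.lights_off is None else float(rec.lights_off),
        "presence_intervals": [[float(a), float(b)]
                               for a, b in rec.presence_intervals],
        "streams_file": stream_file,
    }
    path = d / f"{rec.session_id}_manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path


def load_session(manifest_path) -> SessionRecording:
    """Load and validate a session from its manifest.

    Raises :class:`MissingFileError` when the stream file is absent,
    :class:`UnknownChannelError` for channels outside the schema and
    :class:`NonMonotoneTimestampError` (naming the offending row) when a
    channel's timestamps are not strictly increasing.
    """
    mp = pathlib.Path(manifest_path)
    if not mp.exists():
        raise MissingFileError(f"manifest not found: {mp}")
    manifest = yaml.safe_load(mp.read_text())
    sf = mp.parent / manifest["streams_file"]
    if not sf.exists():
        raise MissingFileError(f"stream file not found: {sf}")
    if sf.suffix == ".parquet":
        frame = pd.read_parquet(sf)
    else:
        frame = pd.read_csv(sf)
    required = {"channel", "t_seconds", "value_c"}
    if not required.issubset(frame.columns):
        raise SchemaError(f"stream table must have columns {sorted(required)}")

    streams = {}
    for channel, grp in frame.groupby("channel", sort=True):
        if channel not in CHANNEL_SPECS:
            raise UnknownChannelError(f"unknown channel {channel!r}")
        t = grp["t_seconds"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            row = int(grp.index[bad[0] + 1])
            raise NonMonotoneTimestampError(
                f"channel {channel!r}: non-increasing timestamp at row {row}")
        rate, res = CHANNEL_SPECS[channel]
        streams[channel] = RawStream(channel, t,
                                     grp["value_c"].to_numpy(dtype=float),
                                     rate, res)
    return SessionRecording(
        subject_id=manifest["subject_id"], session_id=manifest["session_id"],
        setting=manifest["setting"], streams=streams,
        presence_intervals=[list(iv) for iv in manifest["presence_intervals"]],
        lights_off=manifest.get("lights_off"),
        duration_minutes=float(manifest.get("duration_minutes") or 0.0))


def write_study(fixture: StudyFixture, directory, fmt: str = "csv") -> pathlib.Path:
    """Write every session plus a study manifest; returns its path."""
    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifests = [str(write_session(rec, d, fmt=fmt).name)
                 for rec in fixture.sessions]
    study = {
        "seed": int(fixture.seed),
        "participants": [asdict(p) for p in fixture.participants],
        "session_manifests": manifests,
    }
    path = d / "study_manifest.yaml"
    path.write_text(yaml.safe_dump(study, sort_keys=True))
    return path


def load_study(study_manifest_path) -> StudyFixture:
    mp = pathlib.Path(study_manifest_path)
    if not mp.exists():
        raise MissingFileError(f"study manifest not found: {mp}")
    study = yaml.safe_load(mp.read_text())
    participants = [Participant(**p) for p in study["participants"]]
    sessions = [load_session(mp.parent / m) for m in study["session_manifests"]]
    return StudyFixture(participants=participants, sessions=sessions,
                        seed=int(study["seed"]))


def write_feature_table(df: pd.DataFrame, path) -> None:
    path = pathlib.Path(path)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path) -> pd.DataFrame:
    path = pathlib.Path(path)
    if not path.exists():
        raise MissingFileError(f"feature table not found: {path}")
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run from scratch."""

    seed: int = 0
    n_home_subjects: int = 20
    home_nights: int = 5
    n_lab_subjects: int = 20
    lab_nights: int = 2
    duration_minutes: float = 240.0
    physio: dict = field(default_factory=dict)      # PhysioParams overrides
    artifacts: Optional[dict] = None                # ArtifactSpec overrides / None
    oscillation_threshold: float = 2.0
    quality_threshold: float = 0.80
    cv_k: int = 5
    tuning_budget: int = 30
    learning_fractions: tuple = (0.2, 0.4, 0.6, 0.8, 1.0)
    hyperparams: dict = field(default_factory=dict)  # HyperparamConfig overrides
    out_dir: str = "bedtherm_run"

    def physio_params(self) -> PhysioParams:
        return PhysioParams(**self.physio)

    def artifact_spec(self) -> Optional[ArtifactSpec]:
        if self.artifacts is None:
            return None
        return ArtifactSpec(**self.artifacts)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["learning_fractions"] = list(self.learning_fractions)
        pathlib.Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(pathlib.Path(path).read_text())
        if "learning_fractions" in d:
            d["learning_fractions"] = tuple(d["learning_fractions"])
        return cls(**d)

    def config_hash(self) -> str:
        import hashlib
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
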