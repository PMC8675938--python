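"""Reading and writing multi-channel SCG/GCG recordings.

A recording is one ECG channel plus three seismocardiogram (linear
acceleration, g) and three gyrocardiogram (angular velocity, deg/s)
channels, time-synchronised at a single sampling rate.  Three on-disk
representations are supported:

``csv``
    One header row with the canonical channel names, one sample per
    row.  Subject metadata (id, sampling rate, label, site) lives in a
    JSON sidecar next to the file (``<stem>.json``).
``edf``
    EDF (16-bit) with one signal per channel; metadata sidecar as for
    CSV (the subject id is also stored in the EDF patient field).
``wfdb``
    WFDB record: text ``.hea`` header plus format-16 ``.dat``.

Channel order in memory is always canonical regardless of file order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

from . import _edf, _wfdb
from .errors import ChannelMissingError, FormatError, ValidationError

#: canonical channel order; ECG first, then SCG x/y/z, then GCG x/y/z
CHANNEL_NAMES = ("ecg", "scg_x", "scg_y", "scg_z", "gcg_x", "gcg_y", "gcg_z")
SCG_CHANNELS = ("scg_x", "scg_y", "scg_z")
GCG_CHANNELS = ("gcg_x", "gcg_y", "gcg_z")
LABELS = ("CAD", "nonCAD", "unknown")

#: minimum duration (s) for a recording to enter the analysis pipeline
MIN_PIPELINE_DURATION_S = 30.0


@dataclass
class RawRecording:
    """A synchronised 7-channel recording for one subject.

    ``annotations`` optionally carries ground-truth beat times
    (seconds) when the recording is synthetic; real recordings leave
    it empty.
    """

    subject_id: str
    fs: float
    channels: Dict[str, np.ndarray]
    label: str = "unknown"
    site: Optional[str] = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.label not in LABELS:
            raise ValidationError(f"label must be one of {LABELS}, got {self.label!r}")
        missing = [c for c in CHANNEL_NAMES if c not in self.channels]
        if missing:
            raise ChannelMissingError(missing[0])
        ordered = {}
        n = None
        for name in CHANNEL_NAMES:
            x = np.asarray(self.channels[name], dtype=float)
            if x.ndim != 1 or x.size == 0:
                raise ValidationError(f"channel {name!r} must be a non-empty 1-D array")
            if n is None:
                n = x.size
            elif x.size != n:
                raise ValidationError(
                    f"channel {name!r} has {x.size} samples, expected {n}"
                )
            ordered[name] = x
        self.channels = ordered

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def is_pipeline_eligible(self) -> bool:
        return self.duration_s >= MIN_PIPELINE_DURATION_S

    def checksum(self) -> str:
        """SHA-256 over the raw samples; used to detect duplicated subjects."""
        h = hashlib.sha256()
        for name in CHANNEL_NAMES:
            h.update(np.ascontiguousarray(self.channels[name]).tobytes())
        return h.hexdigest()


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        return json.loads(sidecar.read_text())
    return {}


def _write_sidecar(rec: RawRecording, path: Path) -> None:
    meta = {
        "subject_id": rec.subject_id,
        "fs": rec.fs,
        "label": rec.label,
        "site": rec.site,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_recording(path: Union[str, Path], format: Optional[str] = None) -> RawRecording:
    """Read a 7-channel recording from ``csv``, ``edf`` or ``wfdb``.

    ``format`` defaults to the file extension (a ``.hea`` path selects
    WFDB).  The label comes from the JSON sidecar when present, else
    ``unknown``.
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".edf": "edf", ".hea": "wfdb", ".dat": "wfdb"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise FormatError(f"cannot infer format from {path.name!r}")
    if not (path.exists() or format == "wfdb"):
        raise FileNotFoundError(path)
    meta = _read_sidecar(path)

    if format == "csv":
        frame = pd.read_csv(path)
        channels = {}
        for name in CHANNEL_NAMES:
            if name not in frame.columns:
                raise ChannelMissingError(name)
            channels[name] = frame[name].to_numpy(dtype=float)
        fs = float(meta.get("fs", 1000.0))
    elif format == "edf":
        names, signals, fs_list, patient = _edf.read_edf(path)
        rates = set(fs_list)
        if len(rates) > 1:
            raise FormatError(f"mixed sampling rates in EDF: {sorted(rates)}")
        fs = float(rates.pop())
        chan_map = dict(zip(names, signals))
        channels = {}
        for name in CHANNEL_NAMES:
            if name not in chan_map:
                raise ChannelMissingError(name)
            channels[name] = chan_map[name]
        meta.setdefault("subject_id", patient or path.stem)
        fs = float(meta.get("fs", fs))
    elif format == "wfdb":
        base = path.with_suffix("") if path.suffix in (".hea", ".dat") else path
        names, signals, fs = _wfdb.read_record(base)
        chan_map = dict(zip(names, signals))
        channels = {}
        for name in CHANNEL_NAMES:
            if name not in chan_map:
                raise ChannelMissingError(name)
            channels[name] = chan_map[name]
        meta = _read_sidecar(base.with_suffix(".hea"))
    else:
        raise FormatError(f"unknown format {format!r}")

    return RawRecording(
        subject_id=str(meta.get("subject_id", path.stem)),
        fs=float(meta.get("fs", fs if format != "csv" else fs)),
        channels=channels,
        label=str(meta.get("label", "unknown")),
        site=meta.get("site"),
    )


def write_recording(
    rec: RawRecording, path: Union[str, Path], format: Optional[str] = None
) -> None:
    """Write ``rec`` so that :func:`read_recording` recovers it.

    Sample values round-trip exactly for CSV and to 16-bit quantisation
    for EDF/WFDB.
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".edf": "edf", ".hea": "wfdb", ".dat": "wfdb"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise FormatError(f"cannot infer format from {path.name!r}")
    path.parent.mkdir(parents=True, exist_ok=True)

    if format == "csv":
        frame = pd.DataFrame({name: rec.channels[name] for name in CHANNEL_NAMES})
        frame.to_csv(path, index=False, float_format="%.9g")
        _write_sidecar(rec, path)
    elif format == "edf":
        _edf.write_edf(
            path,
            list(CHANNEL_NAMES),
            [rec.channels[n] for n in CHANNEL_NAMES],
            rec.fs,
            patient=rec.subject_id,
        )
        _write_sidecar(rec, path)
    elif format == "wfdb":
        base = path.with_suffix("") if path.suffix in (".hea", ".dat") else path
        _wfdb.write_record(
            base, list(CHANNEL_NAMES), [rec.channels[n] for n in CHANNEL_NAMES], rec.fs
        )
        _write_sidecar(rec, base.with_suffix(".hea"))
    else:
        raise FormatError(f"unknown format {format!r}")


def read_cohort(directory: Union[str, Path]) -> list:
    """Read every ``*.csv`` recording in ``directory`` (sorted by name)."""
    directory = Path(directory)
    recs = [read_recording(p) for p in sorted(directory.glob("*.csv"))]
    if not recs:
        raise FormatError(f"no recordings found in {directory}")
    return recs


def write_cohort(recs, directory: Union[str, Path]) -> list:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recs:
        p = directory / f"{rec.subject_id}.csv"
        write_recording(rec, p, format="csv")
        paths.append(p)
    return paths
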