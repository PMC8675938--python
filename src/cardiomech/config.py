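"""Run configuration for the SCG/GCG CAD-risk pipeline.

Every numeric default is the value used by the reference protocol:
an order-5 zero-phase Butterworth high-pass at 0.5 Hz, decimation to
250 Hz through an order-8 Chebyshev-I filter, 250-sample interpolated
cardiac cycles concatenated 10 at a time, a 40 Hz analysis ceiling,
5 x 10 block averaging of the time-frequency plane, 100 training
epochs with an 80/20 inner split, and a 0.5 decision threshold.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from .errors import ValidationError


@dataclass
class RunConfig:
    # preprocessing
    highpass_order: int = 5
    highpass_cutoff_hz: float = 0.5
    target_fs: float = 250.0
    # segmentation
    cycle_len: int = 250
    cycles_per_series: int = 10
    q_window_ms: float = 60.0
    min_ibi_s: float = 0.3
    max_ibi_s: float = 2.0
    # synchrosqueezing features
    sst_rows: int = 178
    sst_band_rows: int = 150
    sst_fmin_hz: float = 0.5
    freq_cutoff_hz: float = 40.0
    freq_window: int = 5
    time_window: int = 10
    # classifier
    conv_dropout: float = 0.25
    fc_dropout: float = 0.5
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 100
    train_fraction: float = 0.8
    decision_threshold: float = 0.5
    seed: int = 0
    # channels the classifiers consume (ECG is segmentation-only)
    channels: tuple = ("scg_x", "scg_y", "scg_z", "gcg_x", "gcg_y", "gcg_z")

    def __post_init__(self):
        if self.highpass_order < 1:
            raise ValidationError("highpass_order must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must be in (0, 1)")
        if self.cycle_len * self.cycles_per_series <= 0:
            raise ValidationError("cycle_len and cycles_per_series must be positive")
        if self.freq_cutoff_hz <= self.sst_fmin_hz:
            raise ValidationError("freq_cutoff_hz must exceed sst_fmin_hz")
        self.channels = tuple(self.channels)

    @property
    def series_len(self) -> int:
        return self.cycle_len * self.cycles_per_series

    @property
    def feature_len(self) -> int:
        return (self.sst_band_rows // self.freq_window) * (
            self.cycle_len // self.time_window
        )

    # -- flat key=value serialisation ------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels"] = list(self.channels)
        return d

    def save(self, path: Union[str, Path]) -> None:
        lines = []
        for key, value in self.to_dict().items():
            if isinstance(value, list):
                value = ",".join(value)
            lines.append(f"{key} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RunConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for raw in Path(path).read_text().splitlines():
            raw = raw.strip()
            if not raw or raw.startswith("#"):
                continue
            if "=" not in raw:
                raise ValidationError(f"malformed config line: {raw!r}")
            key, value = (s.strip() for s in raw.split("=", 1))
            if key not in fields:
                raise ValidationError(f"unknown config key: {key!r}")
            kwargs[key] = _parse(fields[key].type, value)
        return cls(**kwargs)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _parse(ftype, value: str):
    if ftype in ("int", int):
        return int(value)
    if ftype in ("float", float):
        return float(value)
    if ftype in ("tuple", tuple):
        return tuple(v for v in value.split(",") if v)
    return value
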