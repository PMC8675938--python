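"""Per-cycle synchrosqueezed intensity features.

Each 2,500-sample series (10 interpolated cycles) is transformed with
the SST, split at the cycle boundaries into 10 planes, truncated to
the sub-40 Hz band (150 rows x 250 columns), block-averaged with
5-row x 10-column windows down to 30 x 25, min-max rescaled to a
[0, 1] intensity image, and flattened row-major into a 750-element
vector — the classifier input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import ShapeError
from .preprocess import CleanRecording
from .segmentation import (
    annotate_beats,
    build_series,
    interpolate_cycle,
    segment_cycles,
)
from .sst import TFPlane, frequency_grid, sst_transform


@dataclass
class FeatureVector:
    """One flattened per-cycle intensity image."""

    subject_id: str
    channel: str
    cycle_index: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ShapeError("feature values must be 1-D")


def split_and_truncate(
    plane: TFPlane,
    cycle_len: int = 250,
    n_cycles: int = 10,
    f_cut: float = 40.0,
    band_rows: int = 150,
) -> List[np.ndarray]:
    """Split a series plane into per-cycle planes and drop rows > 40 Hz.

    Rows above ``f_cut`` are discarded; the remaining band is
    standardised to exactly ``band_rows`` rows (re-gridded along the
    frequency axis if the transform used a different grid).
    """
    if plane.values.shape[1] != cycle_len * n_cycles:
        raise ShapeError(
            f"plane has {plane.values.shape[1]} columns, expected {cycle_len * n_cycles}"
        )
    keep = plane.freq_axis <= f_cut * (1 + 1e-9)
    band = plane.values[keep]
    f_band = plane.freq_axis[keep]
    if band.shape[0] != band_rows:
        if band.shape[0] < 2:
            raise ShapeError("fewer than 2 rows below the frequency cut-off")
        target = np.geomspace(f_band[0], f_band[-1], band_rows)
        regrid = np.empty((band_rows, band.shape[1]))
        for j in range(band.shape[1]):
            regrid[:, j] = np.interp(target, f_band, band[:, j])
        band = regrid
    return [band[:, k * cycle_len : (k + 1) * cycle_len] for k in range(n_cycles)]


def reduce_to_image(
    cycle_plane: np.ndarray, f_win: int = 5, t_win: int = 10
) -> np.ndarray:
    """Non-overlapping block mean, then min-max rescale to [0, 1].

    A 150 x 250 plane becomes a 30 x 25 intensity image.  An
    all-constant plane maps to all zeros.
    """
    m = np.asarray(cycle_plane, dtype=float)
    if m.ndim != 2 or m.shape[0] % f_win or m.shape[1] % t_win:
        raise ShapeError(
            f"plane shape {m.shape} not divisible by windows ({f_win}, {t_win})"
        )
    r, c = m.shape[0] // f_win, m.shape[1] // t_win
    blocks = m.reshape(r, f_win, c, t_win).mean(axis=(1, 3))
    lo, hi = blocks.min(), blocks.max()
    if hi - lo == 0:
        return np.zeros_like(blocks)
    return (blocks - lo) / (hi - lo)


def flatten(image: np.ndarray, expected_shape=(30, 25)) -> np.ndarray:
    """Row-major flattening of an intensity image."""
    image = np.asarray(image, dtype=float)
    if image.shape != tuple(expected_shape):
        raise ShapeError(f"image shape {image.shape}, expected {tuple(expected_shape)}")
    return image.reshape(-1)


def extract_features(
    rec: CleanRecording, cfg: RunConfig = None
) -> Dict[str, List[FeatureVector]]:
    """Full feature extraction for one preprocessed recording.

    Beats are annotated once on the ECG; every SCG/GCG channel is then
    segmented on the same Q points, so each series yields exactly 10
    feature vectors per channel.
    """
    cfg = cfg or RunConfig()
    beats = annotate_beats(
        rec.channels["ecg"], rec.fs, cfg.min_ibi_s, cfg.max_ibi_s, cfg.q_window_ms
    )
    freqs = frequency_grid(
        rec.fs, cfg.sst_rows, cfg.sst_band_rows, cfg.sst_fmin_hz, cfg.freq_cutoff_hz
    )
    out: Dict[str, List[FeatureVector]] = {}
    for channel in cfg.channels:
        cycles = segment_cycles(rec.channels[channel], beats.q_indices)
        cycles = [c for c in cycles if c.size >= 2]
        interp = [interpolate_cycle(c, cfg.cycle_len) for c in cycles]
        series_list = build_series(interp, rec.subject_id, channel, cfg.cycle_len)
        vectors: List[FeatureVector] = []
        for s_idx, series in enumerate(series_list):
            plane = sst_transform(series.series, rec.fs, freqs)
            per_cycle = split_and_truncate(
                plane, cfg.cycle_len, cfg.cycles_per_series,
                cfg.freq_cutoff_hz, cfg.sst_band_rows,
            )
            for k, cp in enumerate(per_cycle):
                image = reduce_to_image(cp, cfg.freq_window, cfg.time_window)
                vectors.append(
                    FeatureVector(
                        subject_id=rec.subject_id,
                        channel=channel,
                        cycle_index=s_idx * cfg.cycles_per_series + k,
                        values=flatten(
                            image,
                            (cfg.sst_band_rows // cfg.freq_window,
                             cfg.cycle_len // cfg.time_window),
                        ),
                    )
                )
        out[channel] = vectors
    return out


def feature_matrix(vectors: Sequence[FeatureVector]) -> np.ndarray:
    """Stack feature vectors into an (n_cycles, n_features) array."""
    return np.stack([v.values for v in vectors]).astype(np.float32)


def features_to_frame(vectors: Sequence[FeatureVector], label: str = None) -> pd.DataFrame:
    """Tabular export: one row per cycle, 750 feature columns + metadata."""
    data = feature_matrix(vectors)
    frame = pd.DataFrame(data, columns=[f"f{i}" for i in range(data.shape[1])])
    frame.insert(0, "cycle_index", [v.cycle_index for v in vectors])
    frame.insert(0, "channel", [v.channel for v in vectors])
    frame.insert(0, "subject_id", [v.subject_id for v in vectors])
    if label is not None:
        frame["label"] = label
    return frame
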