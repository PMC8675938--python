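"""Baseline-wander removal, normalisation and downsampling.

Each channel is processed in a fixed order: zero-phase order-5
Butterworth high-pass at 0.5 Hz, demeaning and scaling to [-1, 1],
then decimation to 250 Hz through a zero-phase order-8 Chebyshev-I
anti-aliasing filter.  A final demean/rescale restores the [-1, 1]
contract at the output rate (decimation perturbs both slightly).
The ECG channel receives the identical treatment; only its timing is
consumed downstream, which is normalisation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
from scipy import signal

from .config import RunConfig
from .errors import FilterError, ValidationError
from .io import CHANNEL_NAMES, RawRecording


@dataclass
class CleanRecording(RawRecording):
    """A preprocessed recording: 250 Hz, zero-mean channels in [-1, 1]."""


def highpass_zerophase(
    x: np.ndarray, fs: float, order: int = 5, cutoff: float = 0.5
) -> np.ndarray:
    """Forward-backward Butterworth high-pass; output length = input length."""
    x = np.asarray(x, dtype=float)
    padlen = 3 * (order + 1)
    if x.size <= padlen:
        raise FilterError(
            f"signal of {x.size} samples too short for order-{order} "
            f"zero-phase filtering (needs > {padlen})"
        )
    sos = signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, padtype="even", padlen=padlen)


def normalize(x: np.ndarray) -> np.ndarray:
    """Remove the mean, then scale so max |x| = 1; all-zero input unchanged."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot normalize an empty sequence")
    y = x - x.mean()
    peak = np.max(np.abs(y))
    if peak == 0.0:
        return y
    return y / peak


def downsample(x: np.ndarray, fs_in: float, fs_out: float = 250.0) -> np.ndarray:
    """Decimate by an integer factor with an order-8 Chebyshev-I filter.

    The anti-aliasing low-pass (0.05 dB ripple, cut-off at 0.8 x the
    output Nyquist) is applied zero-phase before keeping every q-th
    sample, so the output has ceil(len/q) samples.
    """
    x = np.asarray(x, dtype=float)
    q = fs_in / fs_out
    if abs(q - round(q)) > 1e-9:
        raise ValidationError(
            f"fs_in/fs_out must be an integer, got {fs_in}/{fs_out} = {q}"
        )
    q = int(round(q))
    if q == 1:
        return x.copy()
    return signal.decimate(x, q, n=8, ftype="iir", zero_phase=True)


def preprocess_recording(rec: RawRecording, cfg: RunConfig = None) -> CleanRecording:
    """Filter, normalise and downsample all 7 channels of a recording."""
    cfg = cfg or RunConfig()
    clean: Dict[str, np.ndarray] = {}
    for name in CHANNEL_NAMES:
        x = highpass_zerophase(
            rec.channels[name], rec.fs, cfg.highpass_order, cfg.highpass_cutoff_hz
        )
        x = normalize(x)
        x = downsample(x, rec.fs, cfg.target_fs)
        clean[name] = normalize(x)  # restore the contract at the output rate
    return CleanRecording(
        subject_id=rec.subject_id,
        fs=cfg.target_fs,
        channels=clean,
        label=rec.label,
        site=rec.site,
        annotations=dict(rec.annotations),
    )
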