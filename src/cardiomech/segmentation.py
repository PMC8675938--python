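"""ECG-anchored cardiac-cycle segmentation.

R peaks are found with the Pan–Tompkins detector (band-pass 5–15 Hz,
derivative, squaring, 150 ms moving-window integration, dual adaptive
thresholds with search-back), each detection refined to the local ECG
maximum.  The QRS onset (Q) is the ECG minimum in the 60 ms window
ending just before each R.  SCG/GCG channels are cut Q-to-Q into
half-open cycles, linearly resampled to 250 points, and concatenated
in non-overlapping runs of 10 into 2,500-sample series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy import signal

from .errors import (
    InsufficientBeatsError,
    InsufficientCyclesError,
    SegmentationError,
    ValidationError,
)


@dataclass
class BeatAnnotations:
    """Q and R sample indices of the usable beats of one recording."""

    q_indices: np.ndarray
    r_indices: np.ndarray
    fs: float

    def __post_init__(self):
        self.q_indices = np.asarray(self.q_indices, dtype=int)
        self.r_indices = np.asarray(self.r_indices, dtype=int)
        if self.q_indices.size != self.r_indices.size:
            raise ValidationError("q_indices and r_indices must pair up")
        if np.any(np.diff(self.q_indices) <= 0) or np.any(np.diff(self.r_indices) <= 0):
            raise ValidationError("beat indices must be strictly increasing")
        offsets = (self.r_indices - self.q_indices) / self.fs
        if self.q_indices.size and not np.all((offsets > 0) & (offsets <= 0.060)):
            raise ValidationError("each Q must precede its R by 1-60 ms")


@dataclass
class CycleSeries:
    """Ten interpolated cardiac cycles of one channel, concatenated."""

    subject_id: str
    channel: str
    series: np.ndarray
    cycle_len: int = 250

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=float)
        if self.series.size != 10 * self.cycle_len:
            raise ValidationError(
                f"series must hold 10 x {self.cycle_len} samples, got {self.series.size}"
            )

    @property
    def cycle_boundaries(self) -> np.ndarray:
        return np.arange(11) * self.cycle_len


def detect_r_peaks(ecg: Sequence[float], fs: float) -> np.ndarray:
    """Pan–Tompkins R-peak detection.

    Returns R-peak sample indices, each refined to the ECG maximum
    within +/-50 ms of the integrated-signal detection.
    """
    ecg = np.asarray(ecg, dtype=float)
    if not 200 <= fs <= 1000:
        raise ValidationError(f"fs must be within [200, 1000] Hz, got {fs}")
    if ecg.size < int(2 * fs):
        raise InsufficientBeatsError("ECG shorter than 2 s")

    sos = signal.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, ecg)
    # five-point derivative of the classic detector
    kern = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(bp, kern[::-1], mode="same")
    squared = deriv**2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    peaks, _ = signal.find_peaks(mwi, distance=refractory)
    if peaks.size < 2:
        raise InsufficientBeatsError("fewer than 2 candidate peaks on ECG")

    # adaptive dual thresholds (running signal/noise peak estimates)
    spki = float(np.max(mwi[: int(2 * fs)])) * 0.5
    npki = float(np.mean(mwi[: int(2 * fs)])) * 0.5
    detections: List[int] = []
    rr_history: List[float] = []
    last_det = -np.inf
    for p in peaks:
        thr1 = npki + 0.25 * (spki - npki)
        if mwi[p] > thr1:
            detections.append(p)
            spki = 0.125 * mwi[p] + 0.875 * spki
            if len(detections) > 1:
                rr_history.append(detections[-1] - detections[-2])
                rr_history = rr_history[-8:]
            last_det = p
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
            # search-back: accept the peak at half threshold when the
            # expected beat is overdue
            if rr_history:
                rr_avg = float(np.mean(rr_history))
                if p - last_det > 1.66 * rr_avg and mwi[p] > 0.5 * thr1:
                    detections.append(p)
                    spki = 0.25 * mwi[p] + 0.75 * spki
                    rr_history.append(detections[-1] - detections[-2])
                    rr_history = rr_history[-8:]
                    last_det = p

    if len(detections) < 2:
        raise InsufficientBeatsError("fewer than 2 beats detected")

    # refine each detection to the local ECG maximum within +/-50 ms
    half = int(round(0.050 * fs))
    refined = []
    for p in detections:
        lo, hi = max(0, p - half), min(ecg.size, p + half + 1)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.unique(refined)
    if refined.size < 2:
        raise InsufficientBeatsError("fewer than 2 distinct beats detected")
    return refined


def locate_q_points(
    ecg: Sequence[float], r_indices: Sequence[int], fs: float, window_ms: float = 60.0
) -> np.ndarray:
    """QRS onset per beat: the ECG minimum in the window ending at R.

    Beats whose window would leave the signal are dropped.
    """
    ecg = np.asarray(ecg, dtype=float)
    w = max(2, int(round(window_ms / 1000.0 * fs)))
    q_points = []
    for r in np.asarray(r_indices, dtype=int):
        lo = r - w
        if lo < 0:
            continue  # window exits the signal start: drop the beat
        q_points.append(lo + int(np.argmin(ecg[lo:r])))
    return np.asarray(q_points, dtype=int)


def annotate_beats(
    ecg: Sequence[float],
    fs: float,
    min_ibi_s: float = 0.3,
    max_ibi_s: float = 2.0,
    window_ms: float = 60.0,
) -> BeatAnnotations:
    """Detect R, locate Q, and gate beats to physiologic intervals.

    A beat is kept only when the Q-to-Q interval to its successor lies
    in [min_ibi_s, max_ibi_s]; this guards the interpolator against
    missed or false detections.  The final beat (which has no
    successor) is retained as a cycle endpoint.
    """
    r = detect_r_peaks(ecg, fs)
    q = locate_q_points(ecg, r, fs, window_ms)
    r = r[-q.size:] if q.size else r[:0]
    # pair sanity: Q strictly before R
    good = (q < r) & (r - q <= int(round(0.060 * fs)) + 1)
    q, r = q[good], r[good]
    if q.size < 2:
        raise InsufficientBeatsError("fewer than 2 usable beats after Q location")
    ibi = np.diff(q) / fs
    keep = np.ones(q.size, dtype=bool)
    keep[:-1] = (ibi >= min_ibi_s) & (ibi <= max_ibi_s)
    return BeatAnnotations(q_indices=q[keep], r_indices=r[keep], fs=fs)


def segment_cycles(
    x: Sequence[float], q_indices: Sequence[int]
) -> List[np.ndarray]:
    """Cut ``x`` into half-open Q-to-Q cycles.

    Concatenating the cycles reconstructs ``x[q_0:q_last]`` exactly.
    """
    x = np.asarray(x, dtype=float)
    q = np.asarray(q_indices, dtype=int)
    return [x[q[k] : q[k + 1]].copy() for k in range(q.size - 1)]


def interpolate_cycle(cycle: Sequence[float], n_out: int = 250) -> np.ndarray:
    """Linearly resample one cycle onto ``n_out`` equally spaced points.

    The grid spans the first to last sample position inclusive, so the
    endpoints are preserved exactly and an ``n_out``-sample input is
    returned unchanged.
    """
    cycle = np.asarray(cycle, dtype=float)
    if cycle.size < 2:
        raise SegmentationError(f"cycle of {cycle.size} samples cannot be resampled")
    grid = np.linspace(0.0, cycle.size - 1, n_out)
    return np.interp(grid, np.arange(cycle.size), cycle)


def build_series(
    cycles: List[np.ndarray], subject_id: str = "", channel: str = "", cycle_len: int = 250
) -> List[CycleSeries]:
    """Concatenate non-overlapping runs of 10 interpolated cycles.

    ``floor(n/10)`` series are produced; a trailing remainder of fewer
    than 10 cycles is discarded.
    """
    if len(cycles) < 10:
        raise InsufficientCyclesError(
            f"{len(cycles)} cycles available, need at least 10 for one series"
        )
    for c in cycles:
        if len(c) != cycle_len:
            raise ValidationError("build_series expects interpolated cycles")
    out = []
    for g in range(len(cycles) // 10):
        block = np.concatenate(cycles[10 * g : 10 * (g + 1)])
        out.append(
            CycleSeries(subject_id=subject_id, channel=channel, series=block,
                        cycle_len=cycle_len)
        )
    return out
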