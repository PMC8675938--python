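"""Synchrosqueezing wavelet transform (SST).

A continuous wavelet transform with an analytic Morlet wavelet is
sharpened by reallocating each coefficient to its instantaneous
frequency — the phase-transform estimate Im(dW/dt / W) / 2 pi.  For a
pure tone this collapses the cone of wavelet responses onto a single
frequency row, which is the property the downstream features rely on.

The frequency grid is geometric (constant ratio) with a fixed number
of rows inside the analysis band (default 150 rows in [0.5, 40] Hz)
plus a geometric continuation up to Nyquist (28 more rows by default,
178 in total), so truncating the plane at the band edge leaves an
exact, configuration-independent row count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

from .errors import ShapeError, ValidationError

#: Morlet centre frequency (rad/sample at unit scale)
MORLET_MU = 6.0


@dataclass
class TFPlane:
    """A non-negative time-frequency magnitude plane."""

    values: np.ndarray  # (n_freqs, n_times), magnitudes
    freq_axis: np.ndarray  # Hz per row, increasing

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.freq_axis = np.asarray(self.freq_axis, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.freq_axis.size:
            raise ShapeError("values rows must match freq_axis length")
        if np.any(np.diff(self.freq_axis) <= 0):
            raise ValidationError("freq_axis must be strictly increasing")


def frequency_grid(
    fs: float = 250.0,
    n_rows: int = 178,
    band_rows: int = 150,
    f_min: float = 0.5,
    f_cut: float = 40.0,
) -> np.ndarray:
    """Geometric frequency axis with ``band_rows`` rows in [f_min, f_cut]."""
    if not 0 < f_min < f_cut < fs / 2:
        raise ValidationError("need 0 < f_min < f_cut < Nyquist")
    if band_rows < 2 or n_rows < band_rows:
        raise ValidationError("need n_rows >= band_rows >= 2")
    low = np.geomspace(f_min, f_cut, band_rows)
    if n_rows == band_rows:
        return low
    high = np.geomspace(f_cut, fs / 2, n_rows - band_rows + 1)[1:]
    return np.concatenate([low, high])


def cwt_morlet(x: np.ndarray, fs: float, freqs: np.ndarray, mu: float = MORLET_MU):
    """Analytic-Morlet CWT evaluated at the given frequencies.

    Returns ``(W, dW)`` where ``dW`` is the time derivative of ``W``
    (both complex, shape ``(len(freqs), len(x))``), computed in the
    Fourier domain on a reflect-padded copy of the signal.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    pad = min(n, max(64, n // 2))
    xp = np.pad(x, pad, mode="reflect")
    m = next_fast_len(xp.size)
    xp = np.pad(xp, (0, m - xp.size))
    X = fft(xp)
    omega = 2 * np.pi * np.fft.fftfreq(m)  # rad/sample
    scales = mu * fs / (2 * np.pi * np.asarray(freqs, dtype=float))
    # analytic wavelet: support on positive frequencies only
    arg = scales[:, None] * omega[None, :]
    psi_hat = np.exp(-0.5 * (arg - mu) ** 2) * (omega[None, :] > 0)
    W = ifft(X[None, :] * psi_hat, axis=1)
    dW = ifft(X[None, :] * psi_hat * (1j * omega)[None, :], axis=1)
    return W[:, pad : pad + n], dW[:, pad : pad + n]


def sst_transform(
    series,
    fs: float = 250.0,
    freqs: np.ndarray = None,
    mu: float = MORLET_MU,
    gamma_rel: float = 1e-8,
) -> TFPlane:
    """Synchrosqueezed magnitude plane of a 1-D series.

    Coefficients with magnitude above ``gamma_rel`` times the plane
    maximum are reallocated to the grid row nearest (geometrically)
    their instantaneous frequency; the rest are discarded.
    """
    x = np.asarray(getattr(series, "series", series), dtype=float)
    if x.ndim != 1:
        raise ShapeError("sst_transform expects a 1-D series")
    if not np.all(np.isfinite(x)):
        raise ValidationError("series contains non-finite samples")
    if freqs is None:
        freqs = frequency_grid(fs)
    freqs = np.asarray(freqs, dtype=float)
    n = x.size
    out = np.zeros((freqs.size, n))
    if not np.any(x):
        return TFPlane(values=out, freq_axis=freqs)

    W, dW = cwt_morlet(x, fs, freqs, mu)
    mag = np.abs(W)
    gamma = gamma_rel * mag.max()
    good = mag > gamma
    with np.errstate(divide="ignore", invalid="ignore"):
        f_inst = fs * np.imag(dW / W) / (2 * np.pi)
    good &= np.isfinite(f_inst) & (f_inst > 0)

    # geometric bin edges around each grid frequency
    edges = np.empty(freqs.size + 1)
    edges[1:-1] = np.sqrt(freqs[:-1] * freqs[1:])
    edges[0] = freqs[0] ** 2 / edges[1]
    edges[-1] = freqs[-1] ** 2 / edges[-2]
    rows = np.searchsorted(edges, f_inst[good]) - 1
    inside = (rows >= 0) & (rows < freqs.size)
    cols = np.broadcast_to(np.arange(n), mag.shape)[good]
    np.add.at(out, (rows[inside], cols[inside]), mag[good][inside])
    return TFPlane(values=out, freq_axis=freqs)
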