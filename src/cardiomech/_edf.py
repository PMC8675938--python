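"""Minimal EDF (European Data Format) reader/writer.

Implements the fixed-layout ASCII header plus 16-bit little-endian
sample records of the EDF standard — enough to exchange continuous
multi-channel recordings at one sampling rate.  Records are one second
long; a final partial second is padded with the physical minimum and
trimmed on read using the sample count stored in the reserved field.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np

from .errors import FormatError

_DIGMIN, _DIGMAX = -32768, 32767


def _fmt(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path,
    names: Sequence[str],
    signals: Sequence[np.ndarray],
    fs: float,
    patient: str = "",
) -> None:
    path = Path(path)
    ns = len(names)
    n_samples = len(signals[0])
    spr = int(round(fs))  # samples per 1 s record
    if abs(fs - spr) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    n_records = int(np.ceil(n_samples / spr))

    phys_min, phys_max, digital = [], [], []
    for sig in signals:
        sig = np.asarray(sig, dtype=float)
        lo, hi = float(sig.min()), float(sig.max())
        if hi - lo < 1e-12:
            lo, hi = lo - 1.0, hi + 1.0
        gain = (_DIGMAX - _DIGMIN) / (hi - lo)
        d = np.round((sig - lo) * gain) + _DIGMIN
        digital.append(d.astype("<i2"))
        phys_min.append(lo)
        phys_max.append(hi)

    header = b""
    header += _fmt("0", 8)
    header += _fmt(patient, 80)
    header += _fmt("cardiomech", 80)
    header += _fmt("01.01.00", 8)
    header += _fmt("00.00.00", 8)
    header += _fmt(256 * (ns + 1), 8)
    header += _fmt(f"nsamp={n_samples}", 44)  # reserved: exact length
    header += _fmt(n_records, 8)
    header += _fmt(1, 8)  # record duration, seconds
    header += _fmt(ns, 4)
    for name in names:
        header += _fmt(name, 16)
    for _ in names:
        header += _fmt("", 80)  # transducer
    for _ in names:
        header += _fmt("au", 8)  # physical dimension
    for lo in phys_min:
        header += _fmt(f"{lo:.6g}", 8)
    for hi in phys_max:
        header += _fmt(f"{hi:.6g}", 8)
    for _ in names:
        header += _fmt(_DIGMIN, 8)
    for _ in names:
        header += _fmt(_DIGMAX, 8)
    for _ in names:
        header += _fmt("", 80)  # prefiltering
    for _ in names:
        header += _fmt(spr, 8)
    for _ in names:
        header += _fmt("", 32)  # per-signal reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for d in digital:
                chunk = d[r * spr : (r + 1) * spr]
                if chunk.size < spr:
                    chunk = np.concatenate(
                        [chunk, np.full(spr - chunk.size, _DIGMIN, dtype="<i2")]
                    )
                fh.write(chunk.tobytes())


def read_edf(path) -> Tuple[List[str], List[np.ndarray], List[float], str]:
    """Return (names, physical signals, per-signal rates, patient field)."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise FormatError("truncated EDF header")

    def ascii_field(off, width):
        return raw[off : off + width].decode("ascii", "replace").strip()

    patient = ascii_field(8, 80)
    reserved = ascii_field(192, 44)
    n_records = int(ascii_field(236, 8))
    rec_dur = float(ascii_field(244, 8))
    ns = int(ascii_field(252, 4))
    off = 256
    names = [ascii_field(off + 16 * i, 16) for i in range(ns)]
    off += 16 * ns + 80 * ns + 8 * ns
    phys_min = [float(ascii_field(off + 8 * i, 8)) for i in range(ns)]
    off += 8 * ns
    phys_max = [float(ascii_field(off + 8 * i, 8)) for i in range(ns)]
    off += 8 * ns
    dig_min = [int(ascii_field(off + 8 * i, 8)) for i in range(ns)]
    off += 8 * ns
    dig_max = [int(ascii_field(off + 8 * i, 8)) for i in range(ns)]
    off += 8 * ns + 80 * ns
    spr = [int(ascii_field(off + 8 * i, 8)) for i in range(ns)]
    header_bytes = 256 * (ns + 1)

    data = np.frombuffer(raw[header_bytes:], dtype="<i2")
    per_record = sum(spr)
    if data.size < per_record * n_records:
        raise FormatError("EDF data section shorter than header declares")
    data = data[: per_record * n_records].reshape(n_records, per_record)

    n_samples = None
    if reserved.startswith("nsamp="):
        n_samples = int(reserved.split("=", 1)[1])

    signals, rates = [], []
    col = 0
    for i in range(ns):
        sig = data[:, col : col + spr[i]].reshape(-1).astype(float)
        col += spr[i]
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        sig = (sig - dig_min[i]) * gain + phys_min[i]
        if n_samples is not None:
            sig = sig[:n_samples]
        signals.append(sig)
        rates.append(spr[i] / rec_dur)
    return names, signals, rates, patient
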