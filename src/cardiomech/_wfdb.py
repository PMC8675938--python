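"""Minimal WFDB record reader/writer (text ``.hea`` + format-16 ``.dat``).

Supports the subset of the WFDB signal specification this package
writes: a single ``.dat`` file shared by all signals, 16-bit two's
complement little-endian samples, per-signal gain and baseline.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np

from .errors import FormatError

_AMAX = 32000  # leave headroom inside int16


def write_record(base, names: Sequence[str], signals: Sequence[np.ndarray], fs: float):
    base = Path(base)
    record = base.name
    n_samples = len(signals[0])
    lines = [f"{record} {len(names)} {fs:g} {n_samples}"]
    digital = []
    for name, sig in zip(names, signals):
        sig = np.asarray(sig, dtype=float)
        amp = float(np.max(np.abs(sig)))
        gain = _AMAX / amp if amp > 0 else 1.0
        d = np.clip(np.round(sig * gain), -32768, 32767).astype("<i2")
        digital.append(d)
        first = int(d[0])
        checksum = int(np.sum(d.astype(np.int64)) % 65536)
        if checksum >= 32768:
            checksum -= 65536
        lines.append(
            f"{record}.dat 16 {gain:.12g}(0)/au 16 0 {first} {checksum} 0 {name}"
        )
    base.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    interleaved = np.empty(n_samples * len(names), dtype="<i2")
    for i, d in enumerate(digital):
        interleaved[i :: len(names)] = d
    base.with_suffix(".dat").write_bytes(interleaved.tobytes())


def read_record(base) -> Tuple[List[str], List[np.ndarray], float]:
    base = Path(base)
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"malformed WFDB header line: {lines[0]!r}")
    nsig, fs, n_samples = int(head[1]), float(head[2]), int(head[3])

    names, gains, baselines, fmts = [], [], [], []
    for i, ln in enumerate(lines[1 : 1 + nsig]):
        parts = ln.split()
        fmts.append(parts[1])
        gain_spec = parts[2]
        baseline = 0
        if "(" in gain_spec:
            gain_str, rest = gain_spec.split("(", 1)
            baseline = int(rest.split(")", 1)[0])
        else:
            gain_str = gain_spec
        gain_str = gain_str.split("/", 1)[0]
        names.append(parts[-1] if len(parts) >= 9 else f"sig_{i}")
        gains.append(float(gain_str) if float(gain_str) != 0 else 200.0)
        baselines.append(baseline)
    if any(f != "16" for f in fmts):
        raise FormatError(f"unsupported WFDB format(s): {sorted(set(fmts))}")

    data = np.frombuffer(base.with_suffix(".dat").read_bytes(), dtype="<i2")
    if data.size < n_samples * nsig:
        raise FormatError("WFDB data file shorter than header declares")
    data = data[: n_samples * nsig].reshape(n_samples, nsig)
    signals = [
        (data[:, i].astype(float) - baselines[i]) / gains[i] for i in range(nsig)
    ]
    return names, signals, fs
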