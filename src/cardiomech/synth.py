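"""Synthetic two-class SCG/GCG cohorts.

The clinical cohorts this pipeline was designed for are not publicly
released, so this module fabricates recordings with the statistical
structure the pipeline assumes:

* quasi-periodic beats with Gaussian heart-rate variability (i.i.d.
  inter-beat intervals, truncated at +/-3 SD);
* an ECG channel with one sharp QRS-like complex per beat (P wave,
  Q dip at a fixed, known offset before R, R spike, S dip, T wave) so
  that QRS detection and Q localisation can be scored against ground
  truth;
* SCG/GCG channels built from a per-class cycle template — a sum of
  Gabor atoms (Gaussian-windowed cosines) at fixed latencies after the
  cycle onset — repeated each beat with per-cycle amplitude jitter.
  The two classes differ only in the centre frequency and amplitude of
  one mid-systolic atom, and only below the 40 Hz analysis ceiling, so
  the class signal lives exactly where the synchrosqueezed features
  look;
* sinusoidal baseline wander strictly below the 0.5 Hz high-pass
  cut-off, plus white sensor noise.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np

from .errors import SynthesisError, ValidationError
from .io import CHANNEL_NAMES, RawRecording

#: Gabor atoms of the non-CAD cycle template: (latency s, freq Hz, amplitude,
#: Gaussian sigma s).  Latencies are measured from the cycle onset (ECG Q).
BASE_ATOMS: Tuple[Tuple[float, float, float, float], ...] = (
    (0.06, 14.0, 1.0, 0.030),   # systolic ejection burst
    (0.18, 22.0, 0.8, 0.035),   # mid-systolic component (class-informative)
    (0.42, 9.0, 0.5, 0.045),    # early-diastolic component
)
#: index of the atom the CAD class shifts
_CAD_ATOM = 1
#: per-channel deterministic flavour: (amplitude scale, latency shift s)
_CHANNEL_FLAVOUR: Dict[str, Tuple[float, float]] = {
    "scg_x": (1.00, 0.000),
    "scg_y": (0.90, 0.008),
    "scg_z": (1.10, -0.006),
    "gcg_x": (0.80, 0.012),
    "gcg_y": (0.95, -0.010),
    "gcg_z": (1.05, 0.005),
}


@dataclass
class SynthSpec:
    """Parameters of a synthetic cohort.

    ``separation`` scales the CAD class's frequency/amplitude shift of
    the mid-systolic atom; 0 makes the classes identical in
    distribution, 1 is the default "strong" separation (+8 Hz, +40%
    amplitude).
    """

    n_per_class: int = 10
    duration_s: float = 60.0
    fs: float = 1000.0
    hr_mean_bpm: float = 60.0
    hr_sd_bpm: float = 5.0
    separation: float = 1.0
    noise_sd: float = 0.05
    wander_amp: float = 0.5
    wander_freq_hz: float = 0.2
    amp_jitter: float = 0.10
    qr_offset_s: float = 0.030
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValidationError("fs and duration_s must be positive")
        if self.hr_mean_bpm <= 0 or self.hr_sd_bpm < 0:
            raise ValidationError("heart rate mean must be positive, SD non-negative")
        if not 0.0 <= self.separation <= 1.5:
            raise ValidationError("separation must lie in [0, 1.5]")
        if self.wander_freq_hz >= 0.5:
            raise ValidationError(
                "baseline wander must stay below the 0.5 Hz high-pass cut-off"
            )
        f_cad = BASE_ATOMS[_CAD_ATOM][1] + 8.0 * self.separation
        if f_cad >= 40.0:
            raise ValidationError("CAD template frequency must stay below 40 Hz")

    @property
    def mean_ibi_s(self) -> float:
        return 60.0 / self.hr_mean_bpm

    @property
    def ibi_sd_s(self) -> float:
        # heart-rate SD expressed as an interval SD (fractional)
        return (self.hr_sd_bpm / self.hr_mean_bpm) * self.mean_ibi_s


def class_atoms(spec: SynthSpec, class_label: str) -> List[Tuple[float, float, float, float]]:
    """The Gabor atoms of the cycle template for one class."""
    atoms = [list(a) for a in BASE_ATOMS]
    if class_label == "CAD":
        lat, f, amp, sig = atoms[_CAD_ATOM]
        atoms[_CAD_ATOM] = [lat, f + 8.0 * spec.separation, amp * (1 + 0.4 * spec.separation), sig]
    elif class_label != "nonCAD":
        raise ValidationError(f"class_label must be CAD or nonCAD, got {class_label!r}")
    return [tuple(a) for a in atoms]


def _add_gaussians(out: np.ndarray, t: np.ndarray, fs: float, comps) -> None:
    """Add amp*exp(-(t-tc)^2/2s^2)[*cos(2 pi f (t-tc))] atoms in place."""
    n = out.size
    for amp, tc, sigma, freq in comps:
        lo = max(0, int((tc - 5 * sigma) * fs))
        hi = min(n, int((tc + 5 * sigma) * fs) + 1)
        if hi <= lo:
            continue
        tt = t[lo:hi] - tc
        w = amp * np.exp(-0.5 * (tt / sigma) ** 2)
        if freq:
            w = w * np.cos(2 * np.pi * freq * tt)
        out[lo:hi] += w


def _beat_times(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """R-peak times; first beat at 0.5 s, margins of 0.5 s at both ends."""
    times = []
    t = 0.5
    while t <= spec.duration_s - 0.5 + 1e-9:
        times.append(t)
        ibi = rng.normal(spec.mean_ibi_s, spec.ibi_sd_s)
        ibi = float(np.clip(ibi, spec.mean_ibi_s - 3 * spec.ibi_sd_s,
                            spec.mean_ibi_s + 3 * spec.ibi_sd_s))
        t += ibi
    if len(times) < 2:
        raise SynthesisError(
            f"duration {spec.duration_s} s too short for two beats at "
            f"{spec.hr_mean_bpm} bpm"
        )
    return np.asarray(times)


def generate_subject(
    spec: SynthSpec, class_label: str, subject_seed: int, subject_id: str = None
) -> RawRecording:
    """One synthetic 7-channel recording, fully determined by the seed."""
    atoms = class_atoms(spec, class_label)
    rng = np.random.default_rng(subject_seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs

    r_times = _beat_times(spec, rng)
    q_times = r_times - spec.qr_offset_s

    # --- ECG: P, Q, R, S, T per beat --------------------------------------
    ecg = np.zeros(n)
    for tr in r_times:
        _add_gaussians(
            ecg, t, spec.fs,
            [
                (0.12, tr - 0.18, 0.030, 0.0),               # P
                (-0.25, tr - spec.qr_offset_s, 0.006, 0.0),  # Q
                (1.00, tr, 0.009, 0.0),                      # R
                (-0.20, tr + 0.028, 0.007, 0.0),             # S
                (0.25, tr + 0.26, 0.050, 0.0),               # T
            ],
        )

    channels = {"ecg": ecg}
    for name in CHANNEL_NAMES[1:]:
        amp_scale, lat_shift = _CHANNEL_FLAVOUR[name]
        x = np.zeros(n)
        jitter = 1.0 + spec.amp_jitter * rng.standard_normal(len(q_times))
        comps = []
        for k, q in enumerate(q_times):
            for lat, f, amp, sig in atoms:
                comps.append((amp * amp_scale * jitter[k], q + lat + lat_shift, sig, f))
        _add_gaussians(x, t, spec.fs, comps)
        channels[name] = x

    # baseline wander + white noise, on every channel
    for name in CHANNEL_NAMES:
        phase = rng.uniform(0, 2 * np.pi)
        wander = spec.wander_amp * np.sin(2 * np.pi * spec.wander_freq_hz * t + phase)
        noise = spec.noise_sd * rng.standard_normal(n) if spec.noise_sd > 0 else 0.0
        channels[name] = channels[name] + wander + noise

    return RawRecording(
        subject_id=subject_id or f"subj_{subject_seed}",
        fs=spec.fs,
        channels=channels,
        label=class_label,
        site="synthetic",
        annotations={"r_times_s": r_times, "q_times_s": q_times},
    )


def generate_cohort(spec: SynthSpec) -> List[RawRecording]:
    """A balanced labelled cohort; per-subject seeds spawn from ``spec.seed``.

    Cohorts feed the full pipeline, so each recording must host at
    least 12 cardiac cycles (one 10-cycle series plus margin).
    """
    if spec.n_per_class < 2:
        raise SynthesisError("need at least 2 subjects per class")
    if spec.duration_s / spec.mean_ibi_s < 12:
        raise SynthesisError(
            f"duration {spec.duration_s} s holds fewer than 12 cycles at "
            f"{spec.hr_mean_bpm} bpm"
        )
    children = np.random.SeedSequence(spec.seed).spawn(2 * spec.n_per_class)
    seeds = [int(c.generate_state(1)[0]) for c in children]
    cohort = []
    for i in range(spec.n_per_class):
        cohort.append(
            generate_subject(spec, "CAD", seeds[i], subject_id=f"cad_{i + 1:02d}")
        )
    for i in range(spec.n_per_class):
        cohort.append(
            generate_subject(
                spec, "nonCAD", seeds[spec.n_per_class + i],
                subject_id=f"non_{i + 1:02d}",
            )
        )
    return cohort
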