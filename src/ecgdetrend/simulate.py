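"""Synthetic ECG excerpts and artificial baseline wanders.

The study design is semi-synthetic: a trend-free ECG excerpt, min-max
normalized to [0, 1], has a mathematically defined baseline wander added to
it, so the ground truth for the trend-free signal is known exactly. This
module provides both ingredients:

* :func:`generate_synthetic_ecg` — a beat train where each beat is a sum of
  five Gaussian bumps (P, Q, R, S, T) placed relative to the R time, with
  seeded beat-to-beat jitter. It emulates a 250 Hz single-channel excerpt
  with identifiable P-QRS-T morphology; it is not a physiological simulator
  (no respiration coupling, muscle noise, or arrhythmia).
* :func:`make_trend` / :func:`default_trend_suite` — the 12 artificial
  wanders: 10 sinusoids on a uniform 0.05 Hz grid from 0.05 to 0.50 Hz
  (unit amplitude, zero phase) plus one step and one spike, both of unit
  amplitude with onset mid-record at 7 s. The trend amplitudes are expressed
  on the normalized-ECG scale, matching how the wanders are superimposed on
  a [0, 1] signal.

All sinusoid frequencies sit at or below 0.5 Hz, i.e. inside MODWT levels
>= 8 at fs = 250 Hz — the band that level-selective detrending zeroes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import Signal

__all__ = [
    "TrendSpec",
    "DEFAULT_MORPHOLOGY",
    "generate_synthetic_ecg",
    "make_trend",
    "default_trend_suite",
]


#: Per-wave Gaussian bump parameters (offset from R in s, width in s,
#: amplitude in mV). Overridable through the config file; chosen so the R
#: peak dominates and T is the second-largest bump.
DEFAULT_MORPHOLOGY: dict[str, tuple[float, float, float]] = {
    "P": (-0.20, 0.025, 0.15),
    "Q": (-0.035, 0.010, -0.12),
    "R": (0.0, 0.012, 1.0),
    "S": (0.035, 0.010, -0.20),
    "T": (0.30, 0.045, 0.35),
}


@dataclass(frozen=True)
class TrendSpec:
    """Declarative description of one artificial baseline wander.

    kind is one of ``sinusoid`` (uses frequency_hz, amplitude, phase_rad),
    ``step`` (amplitude, onset_s) or ``spike`` (amplitude, onset_s,
    width_samples).
    """

    kind: str
    amplitude: float = 1.0
    frequency_hz: float | None = None
    phase_rad: float = 0.0
    onset_s: float | None = None
    width_samples: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("sinusoid", "step", "spike"):
            raise ValueError(f"unknown trend kind {self.kind!r}")
        if self.kind == "sinusoid":
            if self.frequency_hz is None or self.frequency_hz <= 0:
                raise ValueError("sinusoid trend needs a positive frequency_hz")
        else:
            if self.onset_s is None or self.onset_s < 0:
                raise ValueError(f"{self.kind} trend needs a non-negative onset_s")
        if self.kind == "spike" and self.width_samples < 1:
            raise ValueError("spike width_samples must be >= 1")

    @property
    def label(self) -> str:
        if self.kind == "sinusoid":
            return f"sin{self.frequency_hz:.2f}Hz"
        return f"{self.kind}@{self.onset_s:g}s"


def generate_synthetic_ecg(
    duration_s: float = 14.0,
    fs: float = 250.0,
    heart_rate_bpm: float = 60.0,
    rr_jitter_frac: float = 0.05,
    seed: int = 0,
    morphology: dict[str, tuple[float, float, float]] | None = None,
) -> Signal:
    """Generate a trend-free synthetic ECG excerpt.

    R times advance by 60/heart_rate_bpm seconds scaled by
    (1 + uniform(-rr_jitter_frac, rr_jitter_frac)); each beat contributes
    five Gaussian bumps, with a small seeded per-beat amplitude wobble (2%)
    so successive beats are not carbon copies. Deterministic for a fixed
    seed. Output is in mV and carries no additive baseline trend.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz to resolve QRS morphology")
    if not 30 <= heart_rate_bpm <= 200:
        raise ValueError("heart_rate_bpm must be in [30, 200]")
    if not 0 <= rr_jitter_frac < 0.2:
        raise ValueError("rr_jitter_frac must be in [0, 0.2)")
    morphology = DEFAULT_MORPHOLOGY if morphology is None else morphology

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    rr_mean = 60.0 / heart_rate_bpm
    # First R placed a little inside the record; walk until one beat past the end
    # so edge beats contribute their partial P/T waves.
    r_time = 0.4 * rr_mean
    while r_time < duration_s + rr_mean:
        for offset, width, amp in morphology.values():
            amp = amp * (1.0 + 0.02 * rng.standard_normal())
            x += amp * np.exp(-0.5 * ((t - (r_time + offset)) / width) ** 2)
        r_time += rr_mean * (1.0 + rng.uniform(-rr_jitter_frac, rr_jitter_frac))
    return Signal(x, fs, "synthetic")


def make_trend(spec: TrendSpec, duration_s: float, fs: float) -> Signal:
    """Materialize a trend specification as a sampled signal w[t].

    sinusoid: w[t] = amplitude * sin(2 pi f t + phase);
    step: 0 before onset_s, amplitude from onset_s on;
    spike: amplitude on exactly width_samples samples starting at onset_s.
    """
    n = int(round(duration_s * fs))
    if n < 1:
        raise ValueError("empty trend window")
    if spec.kind == "sinusoid":
        if spec.frequency_hz >= fs / 2:
            raise ValueError(
                f"sinusoid frequency {spec.frequency_hz} Hz >= Nyquist ({fs / 2} Hz)"
            )
        t = np.arange(n) / fs
        w = spec.amplitude * np.sin(2 * np.pi * spec.frequency_hz * t + spec.phase_rad)
    else:
        if spec.onset_s >= duration_s:
            raise ValueError(
                f"onset {spec.onset_s} s outside the {duration_s} s record"
            )
        start = int(round(spec.onset_s * fs))
        w = np.zeros(n)
        if spec.kind == "step":
            w[start:] = spec.amplitude
        else:
            w[start : start + spec.width_samples] = spec.amplitude
    return Signal(w, fs, spec.label)


def default_trend_suite(
    duration_s: float = 14.0,
    fs: float = 250.0,
    amplitude: float = 1.0,
    step_onset_s: float = 7.0,
    spike_onset_s: float = 7.0,
    spike_width_samples: int = 1,
) -> list[TrendSpec]:
    """The 12-trend benchmark suite: sinusoids at 0.05, 0.10, ..., 0.50 Hz
    plus one step and one spike (defaults: unit amplitude, onset 7 s,
    1-sample spike). ``duration_s``/``fs`` are used for validation only."""
    specs = [
        TrendSpec(kind="sinusoid", frequency_hz=round(0.05 * k, 2), amplitude=amplitude)
        for k in range(1, 11)
    ]
    specs.append(TrendSpec(kind="step", amplitude=amplitude, onset_s=step_onset_s))
    specs.append(
        TrendSpec(
            kind="spike",
            amplitude=amplitude,
            onset_s=spike_onset_s,
            width_samples=spike_width_samples,
        )
    )
    for s in specs:  # fail early if the suite does not fit the window
        make_trend(s, duration_s, fs)
    return specs
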