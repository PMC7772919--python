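"""Declarative run configuration.

A single YAML file drives a grid run. Every key is optional; defaults are
the benchmark's study conditions (14-s excerpts at 250 Hz, J = 11, 2-s
trims, the 12-trend suite, all 14 wavelets, the six level ranges that
appear in the comparison figures).

Schema (YAML, all keys optional)::

    duration_s: 14.0        # excerpt length, s
    fs: 250.0               # sampling rate, Hz
    J: 11                   # MODWT depth
    trim_s: 2.0             # guard interval removed per end, s
    seed: 0                 # base seed for all randomness
    n_records: 10           # synthetic-mode record count
    heart_rate_bpm: 60.0
    rr_jitter_frac: 0.05
    wavelets: [db3, sym3]   # subset of the 14 names; default all
    level_ranges: [lv1-7, lv1-8, lv2-8, lv3-8, lv1-9, lv3-9]
    trends:
      amplitude: 1.0
      step_onset_s: 7.0
      spike_onset_s: 7.0
      spike_width_samples: 1
      sinusoid_freqs_hz: [0.05, ..., 0.5]   # default uniform 0.05 grid
      include: [sinusoid, step, spike]      # trend kinds to run
    morphology:             # synthetic-ECG bump overrides
      P: [-0.20, 0.025, 0.15]   # [offset_s, width_s, amplitude_mV]
    qtdb_records: [sel100, sel102]   # record ids for --qtdb mode
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .detrend import LevelRange
from .filters import WAVELET_NAMES
from .signals import Signal, minmax_normalize
from .simulate import DEFAULT_MORPHOLOGY, TrendSpec, generate_synthetic_ecg

__all__ = ["GridConfig", "load_config"]

DEFAULT_LEVEL_RANGES = ("lv1-7", "lv1-8", "lv2-8", "lv3-8", "lv1-9", "lv3-9")


@dataclass
class GridConfig:
    duration_s: float = 14.0
    fs: float = 250.0
    J: int = 11
    trim_s: float = 2.0
    seed: int = 0
    n_records: int = 10
    heart_rate_bpm: float = 60.0
    rr_jitter_frac: float = 0.05
    wavelets: tuple[str, ...] = WAVELET_NAMES
    level_ranges: tuple[str, ...] = DEFAULT_LEVEL_RANGES
    trend_amplitude: float = 1.0
    step_onset_s: float = 7.0
    spike_onset_s: float = 7.0
    spike_width_samples: int = 1
    sinusoid_freqs_hz: tuple[float, ...] = tuple(
        round(0.05 * k, 2) for k in range(1, 11)
    )
    trend_kinds: tuple[str, ...] = ("sinusoid", "step", "spike")
    morphology: dict = field(default_factory=lambda: dict(DEFAULT_MORPHOLOGY))
    qtdb_records: tuple[str, ...] = ()

    @classmethod
    def from_dict(cls, raw: dict) -> "GridConfig":
        raw = dict(raw or {})
        trends = raw.pop("trends", {}) or {}
        kwargs = {}
        for key in (
            "duration_s", "fs", "J", "trim_s", "seed", "n_records",
            "heart_rate_bpm", "rr_jitter_frac",
        ):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if "wavelets" in raw:
            kwargs["wavelets"] = tuple(raw.pop("wavelets"))
        if "level_ranges" in raw:
            kwargs["level_ranges"] = tuple(raw.pop("level_ranges"))
        if "qtdb_records" in raw:
            kwargs["qtdb_records"] = tuple(raw.pop("qtdb_records"))
        if "morphology" in raw:
            morph = dict(DEFAULT_MORPHOLOGY)
            morph.update(
                {k: tuple(v) for k, v in (raw.pop("morphology") or {}).items()}
            )
            kwargs["morphology"] = morph
        for src, dst in (
            ("amplitude", "trend_amplitude"),
            ("step_onset_s", "step_onset_s"),
            ("spike_onset_s", "spike_onset_s"),
            ("spike_width_samples", "spike_width_samples"),
        ):
            if src in trends:
                kwargs[dst] = trends[src]
        if "sinusoid_freqs_hz" in trends:
            kwargs["sinusoid_freqs_hz"] = tuple(trends["sinusoid_freqs_hz"])
        if "include" in trends:
            kwargs["trend_kinds"] = tuple(trends["include"])
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        cfg = cls(**kwargs)
        unknown = [w for w in cfg.wavelets if w not in WAVELET_NAMES]
        if unknown:
            raise ValueError(f"unknown wavelets in config: {unknown}")
        return cfg

    def parsed_level_ranges(self) -> list[LevelRange]:
        return [LevelRange.parse(s) for s in self.level_ranges]

    def trend_suite(self) -> list[TrendSpec]:
        specs: list[TrendSpec] = []
        if "sinusoid" in self.trend_kinds:
            specs += [
                TrendSpec(
                    kind="sinusoid", frequency_hz=f, amplitude=self.trend_amplitude
                )
                for f in self.sinusoid_freqs_hz
            ]
        if "step" in self.trend_kinds:
            specs.append(
                TrendSpec(
                    kind="step",
                    amplitude=self.trend_amplitude,
                    onset_s=self.step_onset_s,
                )
            )
        if "spike" in self.trend_kinds:
            specs.append(
                TrendSpec(
                    kind="spike",
                    amplitude=self.trend_amplitude,
                    onset_s=self.spike_onset_s,
                    width_samples=self.spike_width_samples,
                )
            )
        return specs

    def synthetic_records(self) -> list[Signal]:
        """The normalized synthetic cohort: one excerpt per seed
        seed, seed+1, ..., seed+n_records-1."""
        records = []
        for k in range(self.n_records):
            ecg = generate_synthetic_ecg(
                duration_s=self.duration_s,
                fs=self.fs,
                heart_rate_bpm=self.heart_rate_bpm,
                rr_jitter_frac=self.rr_jitter_frac,
                seed=self.seed + k,
                morphology=self.morphology,
            )
            norm = minmax_normalize(ecg)
            records.append(norm.with_samples(norm.samples, f"synthetic-{self.seed + k}"))
        return records

    def provenance(self) -> dict:
        prov = asdict(self)
        prov["morphology"] = {k: list(v) for k, v in prov["morphology"].items()}
        return prov


def load_config(path: str | Path | None) -> GridConfig:
    """Load a YAML config file; ``None`` gives the defaults."""
    if path is None:
        return GridConfig()
    with open(path) as fh:
        return GridConfig.from_dict(yaml.safe_load(fh) or {})
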