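"""Core signal container and elementwise operations.

A :class:`Signal` is a uniformly sampled 1-D time series with its sampling
rate. The same container carries a raw ECG excerpt (mV), its min-max
normalized version (dimensionless, in [0, 1]), a semi-synthetic excerpt with
an added artificial baseline wander, and the detrended output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Signal",
    "DegenerateSignalError",
    "minmax_normalize",
    "superimpose",
]


class DegenerateSignalError(ValueError):
    """Raised when an operation needs a non-constant signal (e.g. min-max
    normalization of a flat trace, whose range is zero)."""


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled real-valued time series.

    Parameters
    ----------
    samples : array-like of float
        Sample values. Stored as a float64 array; must be non-empty and
        finite.
    fs : float
        Sampling rate in Hz; must be positive.
    label : str
        Free-text provenance (record id, ``"synthetic"``, or a composite
        such as ``"sel100+sin0.30Hz"``).
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float)
        if x.ndim != 1 or x.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(x)):
            raise ValueError("samples contain non-finite values")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        x.setflags(write=False)
        object.__setattr__(self, "samples", x)

    @property
    def n(self) -> int:
        """Number of samples."""
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Record duration in seconds (n / fs)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "Signal":
        """Return a copy with new samples (and optionally a new label)."""
        return replace(
            self, samples=samples, label=self.label if label is None else label
        )


def minmax_normalize(x: Signal) -> Signal:
    """Rescale a signal to the unit interval.

    Implements x_N[t] = (x[t] - x_min) / (x_max - x_min), so the output has
    minimum exactly 0 and maximum exactly 1. Puts excerpts of different
    amplitude on a common scale before trends are injected or errors are
    scored.

    Raises
    ------
    DegenerateSignalError
        If the signal is constant (zero range).
    """
    lo = float(x.samples.min())
    hi = float(x.samples.max())
    if hi <= lo:
        raise DegenerateSignalError(
            f"cannot min-max normalize a constant signal (value={lo})"
        )
    return x.with_samples((x.samples - lo) / (hi - lo))


def superimpose(x_n: Signal, w: Signal) -> Signal:
    """Form the semi-synthetic trace y[t] = x_N[t] + w[t].

    Both signals must have equal length and sampling rate. The label records
    both parents.
    """
    if x_n.n != w.n:
        raise ValueError(f"length mismatch: {x_n.n} vs {w.n}")
    if abs(x_n.fs - w.fs) > 1e-9 * max(x_n.fs, w.fs):
        raise ValueError(f"sampling-rate mismatch: {x_n.fs} vs {w.fs}")
    return Signal(x_n.samples + w.samples, x_n.fs, f"{x_n.label}+{w.label}")
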