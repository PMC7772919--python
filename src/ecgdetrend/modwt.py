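"""Maximal Overlap Discrete Wavelet Transform (MODWT) and its inverse.

The MODWT is an undecimated, shift-equivariant wavelet transform: every
decomposition level produces a coefficient vector of the same length as the
input, the transform is exactly invertible, and the squared norms of the
coefficient vectors partition the energy of the input (a Parseval-type
identity). Level j nominally covers the frequency band
(fs / 2^(j+1), fs / 2^j], so higher levels hold lower frequencies — which is
what makes zeroing high levels a baseline-wander remover.

Implementation: the standard pyramid algorithm with MODWT-rescaled filters
(DWT taps divided by sqrt(2)) and circular (periodic) boundary handling. At
level j the filter is upsampled by inserting 2^(j-1) - 1 zeros between taps;
the upsampled circular convolutions are evaluated directly by modular
indexing, never by materializing the upsampled filter.

Alignment convention: level-j coefficients are produced by
W[j, t] = sum_l h_l V[j-1, (t - 2^(j-1) l) mod N], i.e. filters look
backwards in time and an impulse at sample s produces its first-tap response
at sample s. The inverse uses the adjoint (forward-looking) indexing, which
makes the round trip exact. A different alignment would circularly shift
coefficients but leaves reconstruction — and every trimmed MSE downstream —
unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filters import get_filter_pair
from .signals import Signal

__all__ = [
    "ModwtCoefficients",
    "modwt",
    "imodwt",
    "reconstruct_levels",
    "level_frequency_band",
]

# Modular index matrices are identical for every signal of the same length,
# so cache them across grid cells: key (N, L, 2^(j-1), direction sign).
_IDX_CACHE: dict[tuple[int, int, int, int], np.ndarray] = {}


def _indices(n: int, taps: int, upsample: int, sign: int) -> np.ndarray:
    key = (n, taps, upsample, sign)
    idx = _IDX_CACHE.get(key)
    if idx is None:
        idx = (np.arange(n)[None, :] + sign * upsample * np.arange(taps)[:, None]) % n
        _IDX_CACHE[key] = idx
    return idx


@dataclass(frozen=True)
class ModwtCoefficients:
    """The coefficients of one MODWT: detail vectors W_1..W_J plus the final
    scaling vector V_J, all of length N.

    The sampling rate is carried along so that levels can be labeled with
    their nominal frequency bands.
    """

    details: tuple[np.ndarray, ...]
    scaling: np.ndarray
    wavelet_name: str
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        n = self.scaling.size
        if any(w.size != n for w in self.details):
            raise ValueError("all coefficient vectors must have identical length")

    @property
    def J(self) -> int:
        """Decomposition depth."""
        return len(self.details)

    @property
    def n(self) -> int:
        return self.scaling.size

    def detail(self, j: int) -> np.ndarray:
        """Detail vector W_j (1-based level index)."""
        if not 1 <= j <= self.J:
            raise ValueError(f"level {j} outside 1..{self.J}")
        return self.details[j - 1]

    def energy(self) -> float:
        """sum_j ||W_j||^2 + ||V_J||^2 — equals ||x||^2 for the input x."""
        return float(
            sum(float(w @ w) for w in self.details) + float(self.scaling @ self.scaling)
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (one column per level) for CSV export/inspection."""
        data = {f"W{j}": self.details[j - 1] for j in range(1, self.J + 1)}
        data[f"V{self.J}"] = self.scaling
        return pd.DataFrame(data)


def modwt(x: Signal, wavelet_name: str, J: int) -> ModwtCoefficients:
    """Forward MODWT of ``x`` to depth ``J``.

    Requires 1 <= J <= floor(log2(N)); deeper transforms would upsample the
    filters beyond the record length.
    """
    n = x.n
    if J < 1:
        raise ValueError("J must be >= 1")
    if J > int(math.floor(math.log2(n))):
        raise ValueError(f"J={J} too deep for N={n} (max {int(math.log2(n))})")
    pair = get_filter_pair(wavelet_name)
    g = pair.scaling / np.sqrt(2.0)
    h = pair.wavelet / np.sqrt(2.0)
    taps = g.size
    v = x.samples.astype(float)
    details: list[np.ndarray] = []
    for j in range(1, J + 1):
        idx = _indices(n, taps, 2 ** (j - 1), -1)
        layers = v[idx]
        details.append(h @ layers)
        v = g @ layers
    return ModwtCoefficients(
        details=tuple(details),
        scaling=v,
        wavelet_name=wavelet_name,
        fs=x.fs,
        label=x.label,
    )


def imodwt(c: ModwtCoefficients) -> Signal:
    """Inverse MODWT; reconstructs the signal that produced ``c`` exactly
    (to floating-point roundoff)."""
    pair = get_filter_pair(c.wavelet_name)
    g = pair.scaling / np.sqrt(2.0)
    h = pair.wavelet / np.sqrt(2.0)
    taps = g.size
    n = c.n
    v = c.scaling.astype(float)
    for j in range(c.J, 0, -1):
        idx = _indices(n, taps, 2 ** (j - 1), +1)
        v = h @ c.details[j - 1][idx] + g @ v[idx]
    return Signal(v, c.fs, c.label)


def reconstruct_levels(
    c: ModwtCoefficients, detail_levels, include_scaling: bool = False
) -> Signal:
    """Partial reconstruction from a subset of detail levels.

    Equivalent to inverting a copy of ``c`` with every non-selected detail
    vector (and the scaling vector, unless ``include_scaling``) set to zero.
    Reconstructions over a partition of {1..J} plus a scaling-only
    reconstruction sum to the full inverse, by linearity.
    """
    levels = set(int(j) for j in detail_levels)
    bad = [j for j in levels if not 1 <= j <= c.J]
    if bad:
        raise ValueError(f"levels {sorted(bad)} outside 1..{c.J}")
    zero = np.zeros(c.n)
    kept = tuple(
        c.details[j - 1] if j in levels else zero for j in range(1, c.J + 1)
    )
    return imodwt(
        ModwtCoefficients(
            details=kept,
            scaling=c.scaling if include_scaling else zero,
            wavelet_name=c.wavelet_name,
            fs=c.fs,
            label=c.label,
        )
    )


def level_frequency_band(fs: float, j: int) -> tuple[float, float]:
    """Nominal passband (low, high) in Hz of detail level j:
    (fs / 2^(j+1), fs / 2^j). Bands are dyadic, strictly decreasing in j and
    contiguous between adjacent levels."""
    if j < 1:
        raise ValueError("level must be >= 1")
    return fs / 2.0 ** (j + 1), fs / 2.0**j
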