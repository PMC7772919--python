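"""Independent oracles and fixture builders used across the test suite.

These deliberately take different computational routes than the package:
the MODWT oracle works in the frequency domain (DFT multipliers) while the
package uses time-domain modular-index convolution; the WFDB writer packs
bytes by hand so the package's reader is exercised against independently
constructed files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def modwt_fft(x: np.ndarray, scaling: np.ndarray, wavelet: np.ndarray, J: int):
    """Frequency-domain MODWT: at level j the filter transfer function on
    the N-point DFT grid is the base filter's DFT resampled at bin
    k * 2^(j-1) mod N."""
    n = len(x)
    G = np.fft.fft(scaling / np.sqrt(2.0), n)
    H = np.fft.fft(wavelet / np.sqrt(2.0), n)
    V = np.fft.fft(np.asarray(x, dtype=float))
    k = np.arange(n)
    details = []
    for j in range(1, J + 1):
        m = (k * 2 ** (j - 1)) % n
        details.append(np.fft.ifft(H[m] * V).real)
        V = G[m] * V
    return details, np.fft.ifft(V).real


def count_r_peaks(samples: np.ndarray, fs: float, threshold_frac: float = 0.6) -> int:
    """Brute-force R-peak count: local maxima above a fraction of the global
    maximum, with a 250 ms refractory period."""
    x = np.asarray(samples, dtype=float)
    thr = x.min() + threshold_frac * (x.max() - x.min())
    above = x > thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1])
    if crossings.size == 0:
        return 0
    refractory = int(0.25 * fs)
    peaks = [crossings[0]]
    for c in crossings[1:]:
        if c - peaks[-1] > refractory:
            peaks.append(c)
    return len(peaks)


def write_wfdb_record(
    directory: Path,
    record_id: str,
    channels_mv: np.ndarray,
    fs: float,
    fmt: int = 212,
    gain: float = 200.0,
    baseline: int = 0,
) -> Path:
    """Write a .hea/.dat pair (formats 212 or 16) from mV channel data of
    shape (n_samples, n_sig)."""
    channels_mv = np.atleast_2d(channels_mv.T).T
    n, n_sig = channels_mv.shape
    adc = np.rint(channels_mv * gain + baseline).astype(np.int64)
    interleaved = adc.reshape(-1)  # row-major: frame by frame
    dat = directory / f"{record_id}.dat"
    if fmt == 212:
        if np.any((adc < -2048) | (adc > 2047)):
            raise ValueError("format 212 sample out of 12-bit range")
        vals = interleaved.copy()
        if vals.size % 2:
            vals = np.concatenate([vals, [0]])
        vals = (vals & 0xFFF).astype(np.uint32).reshape(-1, 2)
        s0, s1 = vals[:, 0], vals[:, 1]
        packed = np.empty((len(vals), 3), dtype=np.uint8)
        packed[:, 0] = s0 & 0xFF
        packed[:, 1] = ((s0 >> 8) & 0x0F) | (((s1 >> 8) & 0x0F) << 4)
        packed[:, 2] = s1 & 0xFF
        dat.write_bytes(packed.tobytes())
    elif fmt == 16:
        dat.write_bytes(interleaved.astype("<i2").tobytes())
    else:
        raise ValueError(f"unsupported format {fmt}")
    lines = [f"{record_id} {n_sig} {fs:g} {n}"]
    for i in range(n_sig):
        lines.append(
            f"{record_id}.dat {fmt} {gain:g}({baseline})/mV 12 0 "
            f"{adc[0, i]} 0 0 ECG{i + 1}"
        )
    hea = directory / f"{record_id}.hea"
    hea.write_text("\n".join(lines) + "\n")
    return hea
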