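"""File I/O: WFDB records, CSV signals, and result tables.

The WFDB support is a deliberately small reader for the header (``.hea``)
plus signal (``.dat``) pair used by PhysioNet ECG databases, covering the
two sample encodings that matter here: format 212 (pairs of 12-bit
two's-complement samples packed into 3 bytes — the QT Database encoding)
and format 16 (little-endian int16). Samples are converted to physical
units (mV) via (adc - baseline) / gain. The package never downloads data;
a local directory of records is always supplied by the caller.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import RESULT_COLUMNS, ResultTable
from .signals import Signal

__all__ = [
    "ExcerptSpec",
    "read_wfdb_excerpt",
    "sample_excerpts",
    "read_signal_csv",
    "write_signal_csv",
    "read_results_csv",
    "write_results_csv",
]


@dataclass(frozen=True)
class ExcerptSpec:
    """One excerpt to cut from a record: which channel, where, how long."""

    record_id: str
    channel: int = 0
    start_s: float = 0.0
    duration_s: float = 14.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.start_s < 0:
            raise ValueError("start_s must be non-negative")


@dataclass(frozen=True)
class _WfdbHeader:
    record_id: str
    n_sig: int
    fs: float
    n_samples: int
    dat_file: str
    fmt: int
    gains: tuple[float, ...]
    baselines: tuple[int, ...]


def _parse_header(path: Path) -> _WfdbHeader:
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    first = lines[0].split()
    record_id = first[0].split("/")[0]
    n_sig = int(first[1])
    fs = float(first[2].split("/")[0]) if len(first) > 2 else 250.0
    n_samples = int(first[3]) if len(first) > 3 else 0
    gains, baselines = [], []
    dat_file, fmt = "", 16
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        dat_file = parts[0]
        fmt = int(parts[1].split("x")[0].split(":")[0].split("+")[0])
        gain_field = parts[2] if len(parts) > 2 else "200"
        gain_txt = gain_field.split("/")[0]
        if "(" in gain_txt:
            gain_txt, base_txt = gain_txt.rstrip(")").split("(")
            baseline = int(base_txt)
        else:
            # baseline defaults to the ADC zero (field 5 when present)
            baseline = int(parts[4]) if len(parts) > 4 else 0
        gain = float(gain_txt)
        gains.append(gain if gain != 0 else 200.0)
        baselines.append(baseline)
    return _WfdbHeader(
        record_id, n_sig, fs, n_samples, dat_file, fmt, tuple(gains), tuple(baselines)
    )


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    b = b[: (len(b) // 3) * 3].reshape(-1, 3).astype(np.int32)
    s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * len(b), dtype=np.int32)
    out[0::2] = s0
    out[1::2] = s1
    out[out > 2047] -= 4096  # 12-bit two's complement
    return out[:n_values]


def read_wfdb_excerpt(spec: ExcerptSpec, data_dir: str | Path) -> Signal:
    """Read one channel window from a WFDB record, in mV at native fs.

    Raises ``FileNotFoundError`` for a missing record and ``ValueError``
    when the requested window or channel does not exist.
    """
    data_dir = Path(data_dir)
    hea = data_dir / f"{spec.record_id}.hea"
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    hdr = _parse_header(hea)
    if not 0 <= spec.channel < hdr.n_sig:
        raise ValueError(f"channel {spec.channel} outside 0..{hdr.n_sig - 1}")
    start = int(round(spec.start_s * hdr.fs))
    count = int(round(spec.duration_s * hdr.fs))
    if hdr.n_samples and start + count > hdr.n_samples:
        raise ValueError(
            f"window [{spec.start_s}, {spec.start_s + spec.duration_s}] s "
            f"exceeds record length {hdr.n_samples / hdr.fs} s"
        )
    raw = (data_dir / hdr.dat_file).read_bytes()
    n_values = hdr.n_sig * (hdr.n_samples or (len(raw) // 2))
    if hdr.fmt == 212:
        adc = _decode_212(raw, n_values)
    elif hdr.fmt == 16:
        adc = np.frombuffer(raw, dtype="<i2")[:n_values].astype(np.int32)
    else:
        raise ValueError(f"unsupported WFDB format {hdr.fmt} (supported: 212, 16)")
    chan = adc[spec.channel :: hdr.n_sig][start : start + count]
    if chan.size < count:
        raise ValueError("data file shorter than requested window")
    mv = (chan - hdr.baselines[spec.channel]) / hdr.gains[spec.channel]
    return Signal(mv.astype(float), hdr.fs, spec.record_id)


def record_duration_s(record_id: str, data_dir: str | Path) -> float:
    """Record length in seconds, from the WFDB header."""
    hdr = _parse_header(Path(data_dir) / f"{record_id}.hea")
    if not hdr.n_samples:
        raise ValueError(f"header for {record_id} does not state a sample count")
    return hdr.n_samples / hdr.fs


def sample_excerpts(
    record_ids: list[str],
    duration_s: float = 14.0,
    seed: int = 0,
    record_len_s: float | list[float] = 900.0,
) -> list[ExcerptSpec]:
    """One seeded random excerpt per record: the channel is drawn from
    {0, 1} and the start uniformly so the window fits the record
    (``record_len_s`` is a scalar, e.g. the 15-min QT Database records, or
    one length per record). Deterministic per seed."""
    if not record_ids:
        raise ValueError("record_ids must be non-empty")
    lens = (
        [float(record_len_s)] * len(record_ids)
        if np.isscalar(record_len_s)
        else [float(v) for v in record_len_s]
    )
    if len(lens) != len(record_ids):
        raise ValueError("record_len_s must be scalar or match record_ids")
    rng = np.random.default_rng(seed)
    specs = []
    for rid, rlen in zip(record_ids, lens):
        if rlen < duration_s:
            raise ValueError(f"record {rid} ({rlen} s) shorter than {duration_s} s")
        specs.append(
            ExcerptSpec(
                record_id=rid,
                channel=int(rng.integers(0, 2)),
                start_s=float(rng.uniform(0.0, rlen - duration_s)),
                duration_s=duration_s,
                seed=seed,
            )
        )
    return specs


def write_signal_csv(sig: Signal, path: str | Path) -> Path:
    """Two-column CSV (t_seconds, value) with header."""
    path = Path(path)
    pd.DataFrame({"t_seconds": sig.times, "value": sig.samples}).to_csv(
        path, index=False
    )
    return path


def read_signal_csv(path: str | Path, label: str | None = None) -> Signal:
    """Read a (t_seconds, value) CSV; fs is inferred from the time column."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("t_seconds", "value"):
        if col not in df.columns:
            raise ValueError(f"signal CSV needs columns t_seconds,value ({path})")
    t = df["t_seconds"].to_numpy(float)
    if t.size < 2:
        raise ValueError("signal CSV needs at least two samples")
    dt = np.diff(t)
    if dt.min() <= 0 or np.ptp(dt) > 1e-6 * dt.mean():
        raise ValueError("time column must be uniformly increasing")
    return Signal(
        df["value"].to_numpy(float), 1.0 / dt.mean(), label or path.stem
    )


def write_results_csv(t: ResultTable, path: str | Path) -> Path:
    """Write a tidy result grid; provenance rides along as a JSON comment
    line so the file round-trips losslessly."""
    if t.df.empty:
        raise ValueError("refusing to write an empty result table")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# provenance: {json.dumps(t.provenance)}\n")
        t.df.to_csv(fh, index=False, columns=list(RESULT_COLUMNS))
    return path


def read_results_csv(path: str | Path) -> ResultTable:
    """Inverse of :func:`write_results_csv`."""
    path = Path(path)
    provenance: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# provenance:"):
            provenance = json.loads(first.split(":", 1)[1])
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    df["error"] = df["error"].fillna("")
    return ResultTable(df=df, provenance=provenance)
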