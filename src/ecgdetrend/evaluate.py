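"""MSE scoring and the wavelet x level-range x trend evaluation grid.

One experiment: take a normalized clean excerpt x_N, add one artificial
trend, detrend with one wavelet and one kept level range, and score
MSE = sum_t (x_N[t] - x'[t])^2 / M over the M retained (trimmed) samples,
where x' is the trimmed, renormalized detrended signal and x_N is trimmed to
the same window but NOT renormalized (its scale is the ground truth). The
grid is the Cartesian product over records, wavelets, ranges and trends.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detrend import LevelRange, _trim, detrend_signal, zero_levels
from .modwt import imodwt, modwt
from .signals import DegenerateSignalError, Signal, minmax_normalize, superimpose
from .simulate import TrendSpec, make_trend

__all__ = [
    "mse",
    "EvalResult",
    "ResultTable",
    "GridSummary",
    "run_single_experiment",
    "run_grid",
    "summarize_grid",
]

logger = logging.getLogger(__name__)

#: Tidy-table column order shared by run_grid and the CSV writer.
RESULT_COLUMNS = (
    "record_id",
    "wavelet",
    "keep_lo",
    "keep_hi",
    "trend_kind",
    "trend_freq_hz",
    "mse",
    "M",
    "error",
)


def mse(a, b) -> float:
    """Mean squared difference sum_t (a[t] - b[t])^2 / M between two
    equal-length signals or arrays."""
    xa = a.samples if isinstance(a, Signal) else np.asarray(a, dtype=float)
    xb = b.samples if isinstance(b, Signal) else np.asarray(b, dtype=float)
    if xa.size != xb.size:
        raise ValueError(f"length mismatch: {xa.size} vs {xb.size}")
    if xa.size == 0:
        raise ValueError("empty signals")
    d = xa - xb
    return float(d @ d) / xa.size


@dataclass(frozen=True)
class EvalResult:
    """MSE of one (record, wavelet, level range, trend) cell."""

    record_id: str
    wavelet_name: str
    level_range: LevelRange
    trend: TrendSpec
    mse: float
    M: int
    error: str = ""

    def to_row(self) -> dict:
        return {
            "record_id": self.record_id,
            "wavelet": self.wavelet_name,
            "keep_lo": self.level_range.keep_lo,
            "keep_hi": self.level_range.keep_hi,
            "trend_kind": self.trend.kind,
            "trend_freq_hz": self.trend.frequency_hz
            if self.trend.frequency_hz is not None
            else np.nan,
            "mse": self.mse,
            "M": self.M,
            "error": self.error,
        }


@dataclass
class ResultTable:
    """Tidy result grid plus the provenance (config snapshot, seeds) that
    produced it."""

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RESULT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"result table missing columns {missing}")


def _check_normalized(x_n: Signal) -> None:
    if abs(float(x_n.samples.min())) > 1e-9 or abs(float(x_n.samples.max()) - 1) > 1e-9:
        raise ValueError(
            "x_n must be min-max normalized (min 0, max 1) before superimposing trends"
        )


def run_single_experiment(
    x_n: Signal,
    trend: TrendSpec,
    wavelet_name: str,
    r: LevelRange,
    J: int = 11,
    trim_s: float = 2.0,
) -> EvalResult:
    """Run one grid cell: superimpose -> detrend -> score against the clean
    excerpt trimmed to the same window."""
    _check_normalized(x_n)
    w = make_trend(trend, x_n.duration_s, x_n.fs)
    y = superimpose(x_n, w)
    x_prime = detrend_signal(y, wavelet_name, r, J=J, trim_s=trim_s)
    ref = _trim(x_n.samples, x_n.fs, trim_s)
    return EvalResult(
        record_id=x_n.label,
        wavelet_name=wavelet_name,
        level_range=r,
        trend=trend,
        mse=mse(ref, x_prime.samples),
        M=ref.size,
    )


def run_grid(
    records: list[Signal],
    wavelets: list[str],
    level_ranges: list[LevelRange],
    trends: list[TrendSpec],
    J: int = 11,
    trim_s: float = 2.0,
    provenance: dict | None = None,
) -> ResultTable:
    """Evaluate the full Cartesian product, one row per combination.

    The MODWT of each contaminated signal is computed once per
    (record, trend, wavelet) and shared across level ranges. A failing cell
    (e.g. a degenerate post-trim normalization) is recorded with an ``error``
    string and NaN MSE rather than dropped.
    """
    if not (records and wavelets and level_ranges and trends):
        raise ValueError("records, wavelets, level_ranges and trends must be non-empty")
    rows = []
    for x_n in records:
        _check_normalized(x_n)
        ref = _trim(x_n.samples, x_n.fs, trim_s)
        for trend in trends:
            y = superimpose(x_n, make_trend(trend, x_n.duration_s, x_n.fs))
            for wavelet_name in wavelets:
                coeffs = modwt(y, wavelet_name, J)
                for r in level_ranges:
                    try:
                        raw = imodwt(zero_levels(coeffs, r))
                        x_prime = minmax_normalize(
                            Signal(_trim(raw.samples, y.fs, trim_s), y.fs, y.label)
                        )
                        res = EvalResult(
                            record_id=x_n.label,
                            wavelet_name=wavelet_name,
                            level_range=r,
                            trend=trend,
                            mse=mse(ref, x_prime.samples),
                            M=ref.size,
                        )
                    except (DegenerateSignalError, ValueError) as exc:
                        res = EvalResult(
                            record_id=x_n.label,
                            wavelet_name=wavelet_name,
                            level_range=r,
                            trend=trend,
                            mse=float("nan"),
                            M=ref.size,
                            error=str(exc),
                        )
                    rows.append(res.to_row())
                logger.debug(
                    "grid cell record=%s trend=%s wavelet=%s done",
                    x_n.label,
                    trend.label,
                    wavelet_name,
                )
    df = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    n_err = int((df["error"] != "").sum())
    logger.info("grid complete: %d rows, %d failed cells", len(df), n_err)
    return ResultTable(df=df, provenance=provenance or {})


@dataclass
class GridSummary:
    """Grouped mean MSEs plus the best-performing configuration(s)."""

    table: pd.DataFrame
    #: (wavelet, level-range label) pairs tied for the minimum mean MSE
    #: (ties resolved at 1e-12).
    best: list[tuple[str, str]]
    best_mse: float


def summarize_grid(
    t: ResultTable, group_by: tuple[str, ...] = ("wavelet", "keep_lo", "keep_hi")
) -> GridSummary:
    """Mean MSE per group and the argmin (wavelet, range) configuration.

    Failed cells (NaN MSE) are excluded; groups with no valid cells are
    dropped with a warning. Configurations whose mean MSE is within 1e-12 of
    the minimum are all reported (db3 and sym3 share a filter, so they tie
    exactly whenever both are in the grid).
    """
    df = t.df
    if df.empty:
        raise ValueError("empty result table")
    valid = df[df["mse"].notna()]
    dropped = len(df) - len(valid)
    if dropped:
        logger.warning("summarize_grid: excluding %d failed cells", dropped)
    grouped = (
        valid.groupby(list(group_by), dropna=False)["mse"]
        .agg(mean_mse="mean", n="size")
        .reset_index()
    )
    if grouped.empty:
        raise ValueError("no valid cells to summarize")
    # best (wavelet, range) over per-configuration means, regardless of group_by
    conf = (
        valid.groupby(["wavelet", "keep_lo", "keep_hi"])["mse"].mean().reset_index()
    )
    best_mse = float(conf["mse"].min())
    ties = conf[conf["mse"] <= best_mse + 1e-12]
    best = [
        (row.wavelet, f"lv{int(row.keep_lo)}-{int(row.keep_hi)}")
        for row in ties.itertuples()
    ]
    return GridSummary(table=grouped, best=sorted(best), best_mse=best_mse)
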