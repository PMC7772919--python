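"""MSE scoring, single experiments, the evaluation grid, and summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ecgdetrend import (
    LevelRange,
    TrendSpec,
    default_trend_suite,
    mse,
    run_grid,
    run_single_experiment,
    summarize_grid,
)
from ecgdetrend.config import GridConfig


def test_mse_examples():
    assert mse([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert mse([0.0, 0.0], [1.0, 1.0]) == 1.0
    with pytest.raises(ValueError):
        mse([1.0], [1.0, 2.0])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    arrays(np.float64, st.integers(1, 400), elements=st.floats(-100, 100)),
)
def test_mse_matches_naive_loop(a):
    rng = np.random.default_rng(a.size)
    b = a + rng.standard_normal(a.size)
    naive = sum((float(x) - float(y)) ** 2 for x, y in zip(a, b)) / a.size
    assert mse(a, b) == pytest.approx(naive, rel=1e-12, abs=1e-15)
    assert mse(a, b) >= 0.0


def test_identity_path_gives_zero_mse():
    """Zero-amplitude trend plus a keep-everything level range is the
    identity, so the only possible error source is renormalization over the
    trimmed window. Seed 1 gives a record whose extremes lie inside the
    retained 10 s, making renormalization a no-op too."""
    from ecgdetrend import generate_synthetic_ecg, minmax_normalize

    x_n = minmax_normalize(generate_synthetic_ecg(seed=1))
    inner = x_n.samples[500:3000]
    assert inner.min() == 0.0 and inner.max() == 1.0  # fixture precondition
    res = run_single_experiment(
        x_n.with_samples(x_n.samples, "synthetic-1"),
        TrendSpec(kind="sinusoid", frequency_hz=0.1, amplitude=0.0),
        "sym3",
        LevelRange(1, 11, keep_scaling=True),
    )
    assert res.mse <= 1e-18
    assert res.M == 2500


def test_db3_sym3_identical_mse(ecg_norm, lv17):
    trend = TrendSpec(kind="sinusoid", frequency_hz=0.2)
    a = run_single_experiment(ecg_norm, trend, "db3", lv17)
    b = run_single_experiment(ecg_norm, trend, "sym3", lv17)
    assert a.mse == b.mse


def test_lv17_beats_lv19_at_retained_band(ecg_norm, lv17):
    """lv1-9 keeps levels 8-9 (0.24-0.98 Hz at fs 250), so a 0.3 Hz trend
    survives and the MSE must exceed the lv1-7 run."""
    trend = TrendSpec(kind="sinusoid", frequency_hz=0.3)
    narrow = run_single_experiment(ecg_norm, trend, "sym3", lv17)
    wide = run_single_experiment(ecg_norm, trend, "sym3", LevelRange(1, 9))
    assert narrow.mse < wide.mse


def test_unnormalized_record_rejected(lv17):
    from ecgdetrend import generate_synthetic_ecg

    raw = generate_synthetic_ecg(seed=0)  # mV scale, not normalized
    with pytest.raises(ValueError, match="normalized"):
        run_single_experiment(
            raw, TrendSpec(kind="sinusoid", frequency_hz=0.1), "db1", lv17
        )


@pytest.fixture(scope="module")
def small_grid():
    cfg = GridConfig(n_records=2, seed=0)
    records = cfg.synthetic_records()
    ranges = [LevelRange(1, 7), LevelRange(1, 9)]
    table = run_grid(records, ["db1", "db3", "sym3"], ranges, default_trend_suite())
    return records, ranges, table


def test_grid_shape_and_determinism(small_grid):
    records, ranges, table = small_grid
    # 2 records x 3 wavelets x 2 ranges x 12 trends
    assert len(table.df) == 144
    key = ["record_id", "wavelet", "keep_lo", "keep_hi", "trend_kind", "trend_freq_hz"]
    assert not table.df.duplicated(subset=key).any()
    rerun = run_grid(records, ["db1", "db3", "sym3"], ranges, default_trend_suite())
    np.testing.assert_array_equal(
        table.df["mse"].to_numpy(), rerun.df["mse"].to_numpy()
    )
    assert (table.df["error"] == "").all()
    assert (table.df["M"] == 2500).all()


def test_grid_matches_single_experiments(small_grid):
    records, ranges, table = small_grid
    trend = TrendSpec(kind="sinusoid", frequency_hz=0.15)
    single = run_single_experiment(records[1], trend, "db3", ranges[0])
    row = table.df.query(
        "record_id == @records[1].label and wavelet == 'db3' and keep_lo == 1 "
        "and keep_hi == 7 and trend_freq_hz == 0.15"
    )
    assert len(row) == 1
    assert float(row["mse"].iloc[0]) == pytest.approx(single.mse, rel=1e-12)


def test_summarize_grid_means_and_ties(small_grid):
    _, _, table = small_grid
    summary = summarize_grid(table)
    # brute-force group means
    df = table.df
    for row in summary.table.itertuples():
        sel = df[
            (df["wavelet"] == row.wavelet)
            & (df["keep_lo"] == row.keep_lo)
            & (df["keep_hi"] == row.keep_hi)
        ]
        assert row.mean_mse == pytest.approx(float(sel["mse"].mean()), rel=1e-12)
    # db3 and sym3 tie bit-for-bit: both in the argmin set or neither
    winners = {w for w, _ in summary.best}
    assert ("db3" in winners) == ("sym3" in winners)


def test_summarize_empty_table_raises(small_grid):
    import pandas as pd

    from ecgdetrend import ResultTable
    from ecgdetrend.evaluate import RESULT_COLUMNS

    empty = ResultTable(df=pd.DataFrame(columns=list(RESULT_COLUMNS)))
    with pytest.raises(ValueError):
        summarize_grid(empty)


def test_run_grid_validates_nonempty(small_grid):
    records, ranges, _ = small_grid
    with pytest.raises(ValueError):
        run_grid([], ["db1"], ranges, default_trend_suite())
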