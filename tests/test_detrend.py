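"""Level zeroing, the detrending pipeline, trend extraction, and
impulse-edge localization."""

import numpy as np
import pytest

from ecgdetrend import (
    LevelRange,
    Signal,
    TrendSpec,
    detrend_signal,
    extract_trend,
    localize_impulse_edge,
    make_trend,
    modwt,
    superimpose,
    zero_levels,
)


def test_level_range_parsing_and_validation():
    for text in ("1:7", "1-7", "lv1-7", " LV1-7 "):
        r = LevelRange.parse(text)
        assert (r.keep_lo, r.keep_hi) == (1, 7)
        assert r.label == "lv1-7"
    with pytest.raises(ValueError):
        LevelRange.parse("7:1")
    with pytest.raises(ValueError):
        LevelRange.parse("lv1")
    with pytest.raises(ValueError):
        LevelRange(0, 7)


def test_zero_levels_lv17(ecg_norm, lv17):
    c = modwt(ecg_norm, "sym3", 11)
    z = zero_levels(c, lv17)
    for j in range(1, 8):
        np.testing.assert_array_equal(z.details[j - 1], c.details[j - 1])
    for j in range(8, 12):
        assert np.abs(z.details[j - 1]).max() == 0.0
    assert np.abs(z.scaling).max() == 0.0
    # input untouched
    assert np.abs(c.scaling).max() > 0.0


def test_zero_levels_lv39_and_identity(ecg_norm):
    c = modwt(ecg_norm, "sym3", 11)
    z = zero_levels(c, LevelRange(3, 9))
    zeroed = [1, 2, 10, 11]
    for j in zeroed:
        assert np.abs(z.details[j - 1]).max() == 0.0
    for j in range(3, 10):
        np.testing.assert_array_equal(z.details[j - 1], c.details[j - 1])
    ident = zero_levels(c, LevelRange(1, 11, keep_scaling=True))
    for j in range(1, 12):
        np.testing.assert_array_equal(ident.details[j - 1], c.details[j - 1])
    np.testing.assert_array_equal(ident.scaling, c.scaling)
    with pytest.raises(ValueError):
        zero_levels(c, LevelRange(1, 12))


def test_detrend_output_contracts(ecg_norm, lv17):
    w = make_trend(TrendSpec(kind="sinusoid", frequency_hz=0.3), 14.0, 250.0)
    out = detrend_signal(superimpose(ecg_norm, w), "sym3", lv17)
    assert out.n == 2500  # (14 - 2*2) s * 250 Hz
    assert out.samples.min() == 0.0
    assert out.samples.max() == 1.0


def test_detrend_attenuates_pure_low_frequency_sinusoid(lv17):
    """A trend-only input (0.1 Hz unit sinusoid) keeps at most 10% of its
    energy in the trimmed window after lv1-7 detrending."""
    w = make_trend(TrendSpec(kind="sinusoid", frequency_hz=0.1), 14.0, 250.0)
    out = detrend_signal(w, "db3", lv17, normalize=False)
    kept = float(out.samples @ out.samples)
    ref = w.samples[500:3000]
    assert kept <= 0.10 * float(ref @ ref)


def test_db3_sym3_detrend_bit_identical(ecg_norm, lv17):
    w = make_trend(TrendSpec(kind="sinusoid", frequency_hz=0.25), 14.0, 250.0)
    y = superimpose(ecg_norm, w)
    a = detrend_signal(y, "db3", lv17)
    b = detrend_signal(y, "sym3", lv17)
    assert np.array_equal(a.samples, b.samples)


def test_extract_trend_complementarity(ecg_norm, lv17):
    w = make_trend(TrendSpec(kind="step", amplitude=1.0, onset_s=7.0), 14.0, 250.0)
    y = superimpose(ecg_norm, w)
    trend = extract_trend(y, "sym3", lv17)
    retained = detrend_signal(y, "sym3", lv17, trim_s=0.0, normalize=False)
    np.testing.assert_allclose(
        trend.samples + retained.samples, y.samples, atol=1e-9
    )


def test_extract_trend_recovers_step(ecg_norm, lv17):
    """The trend-attributable part of the extraction (isolated via
    linearity: extract(x_n + step) - extract(x_n) == extract(step)) tracks
    the injected step to within 0.1 except near the onset, where a sharp
    edge cannot be represented by low-frequency levels."""
    step = make_trend(TrendSpec(kind="step", amplitude=1.0, onset_s=7.0), 14.0, 250.0)
    y = superimpose(ecg_norm, step)
    isolated = (
        extract_trend(y, "sym3", lv17).samples
        - extract_trend(ecg_norm, "sym3", lv17).samples
    )
    np.testing.assert_allclose(
        isolated, extract_trend(step, "sym3", lv17).samples, atol=1e-9
    )
    t = np.arange(3500) / 250.0
    away = (np.abs(t - 7.0) > 0.5) & (t >= 2.0) & (t < 12.0)
    assert np.abs(isolated - step.samples)[away].max() <= 0.1


def test_extract_trend_energy_without_trend(ecg_norm, lv17):
    trend = extract_trend(ecg_norm, "sym3", lv17)
    assert float(trend.samples @ trend.samples) < float(
        ecg_norm.samples @ ecg_norm.samples
    )


def test_spike_survives_detrend_and_normalization_compresses(ecg_norm, lv17):
    """The renormalization pathology: a 1-sample spike is high-frequency
    content, survives low-level-preserving detrending, becomes the new
    maximum, and compresses the ECG's dynamic range."""
    spike = make_trend(
        TrendSpec(kind="spike", amplitude=3.0, onset_s=7.0), 14.0, 250.0
    )
    out = detrend_signal(superimpose(ecg_norm, spike), "sym3", lv17)
    ref = detrend_signal(ecg_norm, "sym3", lv17)
    # excluding the spike sample, the normalized ECG occupies a much
    # narrower band than the spike-free detrend
    spike_idx = int(np.argmax(out.samples))
    rest = np.delete(out.samples, spike_idx)
    assert np.ptp(rest) < 0.6 * np.ptp(ref.samples)
    # robust rescaling sidesteps the compression
    robust = detrend_signal(
        superimpose(ecg_norm, spike), "sym3", lv17, robust=True
    )
    rest_r = np.delete(robust.samples, int(np.argmax(robust.samples)))
    assert np.ptp(rest_r) > np.ptp(rest)


def test_localize_impulse_edge(ecg_norm):
    spike = make_trend(
        TrendSpec(kind="spike", amplitude=3.0, onset_s=7.0), 14.0, 250.0
    )
    y = superimpose(ecg_norm, spike)
    idx = localize_impulse_edge(y, "db1")
    assert abs(idx - 1750) <= 2  # Haar filter length
    # pure spike on a flat baseline localizes exactly
    pure = Signal(spike.samples, 250.0, "spike")
    assert abs(localize_impulse_edge(pure, "db1") - 1750) <= 1
    # spike-free input returns the steepest QRS transition (near an R peak)
    idx_clean = localize_impulse_edge(ecg_norm, "db1")
    r_samples = np.flatnonzero(ecg_norm.samples > 0.9)
    assert np.min(np.abs(r_samples - idx_clean)) < 10


def test_detrend_trim_validation(lv17):
    short = Signal(np.random.default_rng(0).standard_normal(600), 250.0)
    with pytest.raises(ValueError, match="trim"):
        detrend_signal(short, "db1", lv17, J=9, trim_s=2.0)
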