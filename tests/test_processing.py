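"""dF/F pipeline: sliding percentiles, filtering, detrending, F0/noise."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from whisca import (lowpass_filter, detrend, sliding_percentile,
                    estimate_f0_and_noise, compute_dff, transient_kernel)
from whisca.processing import truncation_correction


def naive_sliding_percentile(x, window, q):
    """Independent loop implementation of the centred truncated window."""
    n = len(x)
    half_lo = window // 2
    half_hi = window - half_lo
    return np.array([np.percentile(x[max(0, t - half_lo):min(n, t + half_hi)], q)
                     for t in range(n)])


@pytest.mark.parametrize("window", [10, 11, 50])
def test_sliding_percentile_matches_naive_oracle(rng, window):
    x = rng.normal(0, 1, 300)
    got = sliding_percentile(x, window, 8.0)
    want = naive_sliding_percentile(x, window, 8.0)
    assert np.allclose(got, want)


def test_lowpass_constant_and_nyquist():
    const = np.full(100, 3.5)
    assert np.allclose(lowpass_filter(const, 5.0, 10.0), 3.5)
    nyq = np.resize([1.0, -1.0], 100)
    out = lowpass_filter(nyq, 5.0, 10.0)
    assert np.abs(out[2:-2]).max() < 1e-12  # alternation annihilated
    with pytest.raises(ValueError):
        lowpass_filter(const, 6.0, 10.0)


def test_lowpass_reduces_noise_variance(rng):
    x = rng.normal(0, 1, 20000)
    for cutoff in (5.0, 2.0):  # binomial branch and Butterworth branch
        y = lowpass_filter(x, cutoff, 10.0)
        assert y.var() < 0.8 * x.var()
        assert abs(y.mean() - x.mean()) < 0.01  # DC gain 1


def test_detrend_constant_and_fallback(rng):
    const = np.full(200, 4.0)
    assert np.allclose(detrend(const, window_frames=50), 0.0)
    x = rng.normal(10, 1, 80)
    with pytest.warns(UserWarning, match="global"):
        out = detrend(x, window_frames=1000)
    assert np.allclose(out, x - np.percentile(x, 8))


def test_detrend_removes_ramp_keeps_events(rng):
    n = 6000
    ramp = np.linspace(0, 2, n)
    x = 100 + ramp + rng.normal(0, 0.05, n)
    k = transient_kernel(0.18, 1.5, 10.0)
    onsets = np.arange(500, n - 200, 800)
    for on in onsets:
        x[on:on + k.size] += 10.0 * k
    out = detrend(x, 1000, 8.0)
    quiet = np.ones(n, dtype=bool)
    for on in onsets:
        quiet[on - 20:on + 120] = False
    assert np.abs(out[quiet] - np.median(out[quiet])).max() < 1.0
    for on in onsets:
        peak = out[on:on + 30].max() - np.median(out[quiet])
        assert abs(peak - 10.0) / 10.0 < 0.05  # events preserved within 5%


def test_f0_constant_trace():
    f0, noise_sd, _ = estimate_f0_and_noise(np.full(300, 100.0), 10.0)
    assert f0 == 100.0 and noise_sd == 0.0


def test_f0_and_noise_on_gaussian_baseline(rng):
    # Monte-Carlo oracle with known sigma: F0 ~ B; noise_sd within 15% of an
    # independently computed corrected sub-70th-percentile truncated SD
    B, sigma = 200.0, 3.0
    x = B + rng.normal(0, sigma, 6000)
    f0, noise_sd, _ = estimate_f0_and_noise(x, 10.0)
    assert abs(f0 - B) < sigma
    nb = x - naive_sliding_percentile(x, 10, 8.0)
    sel = nb < np.percentile(nb, 70)
    oracle = nb[sel].std() * truncation_correction(70.0)
    assert abs(noise_sd - oracle) / oracle < 0.15


def test_dff_constant_trace_is_exactly_zero():
    d = compute_dff(np.full(500, 100.0), 10.0)
    assert np.all(d.dff == 0.0)
    assert d.f0 == 100.0 and d.noise_sd == 0.0 and d.valid


def test_dff_transient_peak_through_full_pipeline(rng):
    # baseline 100 with one transient peaking at 150 -> peak dF/F ~ 0.5
    n = 3000
    x = 100 + rng.normal(0, 1.0, n)
    k = transient_kernel(0.18, 1.5, 10.0)
    x[1200:1200 + k.size] += 50.0 * k
    d = compute_dff(x, 10.0)
    assert abs(d.dff.max() - 0.5) < 0.05


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.floats(min_value=0.1, max_value=50.0))
def test_dff_scale_equivariance(c):
    rng = np.random.default_rng(7)
    x = 100 + rng.normal(0, 2.0, 1500)
    x[400:450] += 30.0
    d1 = compute_dff(x, 10.0)
    d2 = compute_dff(c * x, 10.0)
    assert np.allclose(d1.dff, d2.dff, atol=1e-9)
    assert np.isclose(d2.f0, c * d1.f0)


def test_dff_offset_sensitivity(rng):
    x = 100 + rng.normal(0, 2.0, 1500)
    x[400:450] += 30.0
    d1 = compute_dff(x, 10.0)
    d2 = compute_dff(x + 100.0, 10.0)
    assert not np.allclose(d1.dff, d2.dff)
    assert d2.dff.max() < d1.dff.max()  # larger F0 shrinks dF/F


def test_dff_eventless_mean_small():
    # F0 is the median of sub-70th-percentile noise-band samples, which sits
    # ~0.5 band-SD below the noise mean, so event-free dF/F carries a small
    # positive offset well below the 3 x SD detection threshold
    for seed in (0, 1, 2):
        rng = np.random.default_rng(seed)
        x = 100 + rng.normal(0, 2.0, 6000)
        d = compute_dff(x, 10.0)
        assert 0 <= d.dff.mean() < 0.75 * d.noise_sd


def test_nonpositive_f0_flagged_unusable(rng):
    x = rng.normal(-5.0, 1.0, 1500)
    d = compute_dff(x, 10.0)
    assert not d.valid
    assert np.all(d.dff == 0.0)
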