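"""Generator contracts: determinism, renewal statistics, event counts,
marginal rate conservation, and movie rendering with known motion."""

import dataclasses

import numpy as np
import pytest

from whisca import (SimulationConfig, simulate_behavior, simulate_traces,
                    render_movie, transient_kernel)


@pytest.mark.parametrize("kwargs", [
    dict(whisking_mean_bout_s=0.0),
    dict(whisking_mean_gap_s=-1.0),
    dict(tau_rise_s=2.0, tau_decay_s=1.0),
    dict(shared_drive_weight=1.0),
    dict(neuropil_ratio=1.2),
    dict(event_rate_stationary_hz=-0.1),
    dict(frame_rate_hz=0.0),
    dict(responsive_fraction=1.5),
])
def test_invalid_parameters_rejected(kwargs):
    cfg = dataclasses.replace(SimulationConfig(), **kwargs)
    with pytest.raises(ValueError):
        cfg.validate()


def test_same_seed_gives_identical_outputs():
    cfg = SimulationConfig(n_rois=6, duration_s=60)
    b1, s1 = simulate_behavior(cfg, 5)
    b2, s2 = simulate_behavior(cfg, 5)
    assert np.array_equal(b1, b2) and np.array_equal(s1, s2)
    r1, n1, g1 = simulate_traces(cfg, 5)
    r2, n2, g2 = simulate_traces(cfg, 5)
    assert np.array_equal(r1, r2) and np.array_equal(n1, n2)
    for a, b in zip(g1.event_times, g2.event_times):
        assert np.array_equal(a, b)
    # different seed differs
    b3, _ = simulate_behavior(cfg, 6)
    assert not np.array_equal(b1, b3)


def test_traces_and_behavior_share_the_state_sequence():
    cfg = SimulationConfig(n_rois=3, duration_s=120)
    _, state_b = simulate_behavior(cfg, 9)
    _, _, gt = simulate_traces(cfg, 9)
    assert np.array_equal(state_b, gt.state_sequence)


def test_whisking_fraction_matches_renewal_stationary_fraction():
    # closed form: bout / (bout + gap) = 2 / 8 = 0.25
    cfg = SimulationConfig(duration_s=1000.0, whisking_mean_bout_s=2.0,
                           whisking_mean_gap_s=6.0)
    _, state = simulate_behavior(cfg, 3)
    assert state.size == 10_000
    assert abs(state.mean() - 0.25) < 0.05


def test_zero_rates_give_eventless_baseline():
    cfg = SimulationConfig(n_rois=3, duration_s=60,
                           event_rate_stationary_hz=0.0,
                           event_rate_whisking_hz=0.0,
                           responsive_fraction=0.0,
                           noise_sd=0.0, drift_amplitude=0.0,
                           neuropil_ratio=0.0)
    raw, npil, gt = simulate_traces(cfg, 1)
    assert all(t.size == 0 for t in gt.event_times)
    assert np.allclose(raw, cfg.baseline_f)


def test_noiseless_single_event_peak_equals_amplitude():
    cfg = SimulationConfig(n_rois=1, duration_s=60, noise_sd=0.0,
                           drift_amplitude=0.0, neuropil_ratio=0.0,
                           amplitude_mean=1.0)
    raw, _, gt = simulate_traces(cfg, 1, event_times=[[100]],
                                 event_amplitudes=[[1.0]])
    # sampled kernel is peak-normalised to 1, so peak above baseline is
    # amplitude x baseline
    assert np.isclose(raw.max() - cfg.baseline_f, cfg.baseline_f * 1.0)
    assert np.isclose(raw[0, 99], cfg.baseline_f)


def test_event_count_within_poisson_interval():
    # Poisson counting oracle: rate x time x ROIs = 0.05 * 600 * 50 = 1500
    cfg = SimulationConfig(n_rois=50, duration_s=600,
                           event_rate_stationary_hz=0.05,
                           event_rate_whisking_hz=0.05,
                           responsive_fraction=0.0, shared_drive_weight=0.0)
    _, _, gt = simulate_traces(cfg, 7)
    total = sum(t.size for t in gt.event_times)
    mu = 0.05 * 600 * 50
    half = 2.576 * np.sqrt(mu)  # 99% normal approximation of the Poisson CI
    assert mu - half < total < mu + half


def test_shared_drive_preserves_marginal_rate():
    # the shared train substitutes for, not adds to, independent events
    cfg = SimulationConfig(n_rois=60, duration_s=600,
                           event_rate_stationary_hz=0.05,
                           event_rate_whisking_hz=0.3,
                           responsive_fraction=1.0, shared_drive_weight=0.6,
                           onset_event_probability=0.0)
    _, _, gt = simulate_traces(cfg, 13)
    whisk = gt.state_sequence == 1
    n_whisk_events = sum(np.isin(t, np.flatnonzero(whisk)).sum()
                         for t in gt.event_times)
    mu = 0.3 / 10.0 * whisk.sum() * 60
    assert abs(n_whisk_events - mu) < 4 * np.sqrt(mu)


def test_render_static_anatomy_without_motion():
    cfg = SimulationConfig(n_rois=4, duration_s=2, movie_noise_sd=0.5)
    raw, _, gt = simulate_traces(cfg, 2)
    movie, gt = render_movie(raw, cfg, 2, ground_truth=gt)
    assert np.all(gt.applied_shifts == 0)
    spread = movie.anatomical.std(axis=0).max()
    assert spread < 5 * cfg.movie_noise_sd


def test_render_constant_trace_gives_constant_spot():
    cfg = SimulationConfig(n_rois=1, duration_s=2, movie_noise_sd=0.0)
    const = np.full((1, 20), 80.0)
    movie, gt = render_movie(const, cfg, 3)
    assert np.allclose(movie.functional, movie.functional[0])


def test_render_applied_shift_recovered_by_crosscorrelation_oracle():
    # exhaustive integer-shift cross-correlation on the anatomical channel
    cfg = SimulationConfig(n_rois=5, duration_s=1, movie_noise_sd=0.5)
    raw, _, _ = simulate_traces(cfg, 4)
    shifts = np.zeros((raw.shape[1], 2))
    shifts[3] = (3, -2)
    movie, gt = render_movie(raw, cfg, 4, shifts=shifts)
    ref, frame = movie.anatomical[0], movie.anatomical[3]
    best, best_val = None, -np.inf
    for dy in range(-5, 6):
        for dx in range(-5, 6):
            val = (np.roll(frame, (-dy, -dx), axis=(0, 1)) * ref).sum()
            if val > best_val:
                best, best_val = (dy, dx), val
    assert best == (3, -2)


def test_placement_failure_raises():
    cfg = SimulationConfig(n_rois=500, fov_px=32)
    with pytest.raises(RuntimeError):
        render_movie(np.ones((500, 5)), cfg, 1)


def test_kernel_peak_normalised_and_shape():
    k = transient_kernel(0.18, 1.5, 10.0)
    assert np.isclose(k.max(), 1.0)
    assert k[0] < 0.9 and k[-1] < 0.01
    with pytest.raises(ValueError):
        transient_kernel(1.5, 0.18, 10.0)
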