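"""Transient detection, whisking segmentation, state labelling, activity
summaries and whisking-responsiveness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from whisca import (SimulationConfig, simulate_behavior, detect_transients,
                    detect_whisking_epochs, label_transient_states,
                    summarize_activity, classify_whisking_responsive,
                    whisking_association_mask, WHISKING, SPONTANEOUS)
from whisca.events import WhiskingEpochs, TransientEvent

from conftest import make_dff


def naive_run_detector(x, thr, min_len):
    """Brute-force run-length oracle."""
    events, run = [], []
    for i, v in enumerate(x):
        if v > thr:
            run.append(i)
        else:
            if len(run) >= min_len:
                events.append((run[0], run[-1] + 1))
            run = []
    if len(run) >= min_len:
        events.append((run[0], run[-1] + 1))
    return events


def test_no_events_on_flat_trace():
    d = make_dff(np.zeros(200), noise_sd=0.1)
    assert detect_transients(d) == []


def test_duration_rule_boundary():
    x = np.zeros(200)
    x[50:59] = 0.5  # 9 frames at 5 x SD: below the 10-frame minimum
    assert detect_transients(make_dff(x, noise_sd=0.1)) == []
    x[50:60] = 0.5  # 10 frames: kept
    ev = detect_transients(make_dff(x, noise_sd=0.1))
    assert len(ev) == 1 and (ev[0].onset_frame, ev[0].offset_frame) == (50, 60)


def test_two_pulses_with_subthreshold_gap():
    x = np.zeros(300)
    x[50:62] = 0.5
    x[70:82] = 0.5
    ev = detect_transients(make_dff(x, noise_sd=0.1))
    assert [(e.onset_frame, e.offset_frame) for e in ev] == [(50, 62), (70, 82)]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_detection_matches_run_length_oracle(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 0.1, 400)
    x[rng.integers(0, 300)] += 1.0
    x = np.convolve(x, np.ones(12), mode="same")
    d = make_dff(x, noise_sd=0.1)
    got = [(e.onset_frame, e.offset_frame) for e in detect_transients(d)]
    assert got == naive_run_detector(x, 0.3, 10)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_detection_monotonicity(seed):
    rng = np.random.default_rng(seed)
    x = np.convolve(rng.normal(0, 0.2, 500), np.ones(8), mode="same")
    d = make_dff(x, noise_sd=0.1)
    n_lo = len(detect_transients(d, threshold_sd=2, min_duration_frames=5))
    n_hi = len(detect_transients(d, threshold_sd=3, min_duration_frames=5))
    n_long = len(detect_transients(d, threshold_sd=2, min_duration_frames=10))
    assert n_hi <= n_lo and n_long <= n_lo


def test_zero_noise_sd_on_nonconstant_trace_is_an_error():
    d = make_dff(np.sin(np.arange(100)), noise_sd=0.0)
    with pytest.raises(RuntimeError, match="noise"):
        detect_transients(d)


def test_flat_behavior_has_no_epochs():
    ep = detect_whisking_epochs(np.full(500, 10.0), 10.0)
    assert ep.epochs == []


def test_epoch_merge_rule():
    rng = np.random.default_rng(0)
    b = 50 + rng.normal(0, 1, 600)
    b[200:220] += 40
    b[222:240] += 40  # 2-frame gap, below merge_gap_frames=5
    ep = detect_whisking_epochs(b, 10.0, merge_gap_frames=5)
    covering = [e for e in ep.epochs if e[0] <= 205 and e[1] >= 235]
    assert len(covering) == 1


def test_epoch_recovery_against_ground_truth():
    cfg = SimulationConfig(duration_s=600)
    b, s = simulate_behavior(cfg, 4)
    ep = detect_whisking_epochs(b, 10.0)
    det, gt = ep.mask(), s.astype(bool)
    iou = (det & gt).sum() / (det | gt).sum()
    assert iou >= 0.9


def test_epochs_invariants_enforced():
    with pytest.raises(ValueError):
        WhiskingEpochs(epochs=[(10, 20), (15, 30)], n_frames=50)


def _mk_events(onsets, n=1000):
    return [TransientEvent(roi_id=0, onset_frame=o, offset_frame=o + 12,
                           peak_dff=1.0, peak_frame=o + 3) for o in onsets]


def test_labels_no_epochs_all_spontaneous():
    ev = _mk_events([10, 500])
    ep = WhiskingEpochs(epochs=[], n_frames=1000)
    label_transient_states(ev, ep, 10.0)
    assert all(e.state == SPONTANEOUS for e in ev)


def test_label_boundary_one_second_before_onset():
    ep = WhiskingEpochs(epochs=[(100, 120)], n_frames=1000)
    ev = _mk_events([90, 89, 139, 140])
    label_transient_states(ev, ep, 10.0, pre_s=1.0, post_s=2.0)
    # closed lower bound at onset - 1 s; half-open upper bound 2 s past offset
    assert [e.state for e in ev] == [WHISKING, SPONTANEOUS,
                                     WHISKING, SPONTANEOUS]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_labels_match_interval_membership_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 600
    starts = np.sort(rng.choice(np.arange(20, n - 40, 30), 4, replace=False))
    epochs = [(int(s), int(s + rng.integers(5, 20))) for s in starts]
    ep = WhiskingEpochs(epochs=epochs, n_frames=n)
    onsets = rng.integers(0, n - 15, 12)
    ev = [TransientEvent(0, int(o), int(o) + 12, 1.0, int(o) + 2)
          for o in onsets]
    label_transient_states(ev, ep, 10.0)
    for e in ev:
        member = any(s - 10 <= e.onset_frame < t + 20 for s, t in epochs)
        assert (e.state == WHISKING) == member
    # partition: every event got exactly one label
    assert all(e.state in (WHISKING, SPONTANEOUS) for e in ev)


@pytest.mark.parametrize("which,expected", [
    ("spont", 0.0), ("whisk", 90.0), ("both", 45.0)])
def test_activity_angle_extremes(which, expected):
    n = 6000
    ep = WhiskingEpochs(epochs=[(s, s + 20) for s in range(100, n - 100, 60)],
                        n_frames=n)
    mask = whisking_association_mask(ep, 10.0)
    whisk_frames = np.flatnonzero(mask)[::40]
    stat_frames = np.flatnonzero(~mask)[::40]
    # equal frequencies need counts proportional to state durations
    n_w = len(whisk_frames)
    n_s = int(round(n_w * (~mask).sum() / mask.sum()))
    if which == "spont":
        onsets = stat_frames[:20]
    elif which == "whisk":
        onsets = whisk_frames[:20]
    else:
        onsets = np.concatenate([whisk_frames[:n_w], stat_frames[:n_s]])
    ev = [TransientEvent(0, int(o), int(o) + 12, 1.0, int(o) + 2)
          for o in sorted(onsets)]
    d = make_dff(np.zeros(n))
    summ = summarize_activity(ev, ep, d)
    assert summ.angle_deg == pytest.approx(expected, abs=1.5)


def test_frequency_conservation():
    n = 6000
    ep = WhiskingEpochs(epochs=[(s, s + 20) for s in range(100, n - 100, 80)],
                        n_frames=n)
    rng = np.random.default_rng(3)
    ev = [TransientEvent(0, int(o), int(o) + 12, 1.0, int(o) + 2)
          for o in np.sort(rng.choice(n - 20, 40, replace=False))]
    d = make_dff(np.zeros(n))
    summ = summarize_activity(ev, ep, d)
    freq_total = summ.n_events / (n / 10.0 / 60.0)
    lo = min(summ.freq_stationary, summ.freq_whisking)
    hi = max(summ.freq_stationary, summ.freq_whisking)
    assert lo <= freq_total <= hi


def test_flat_trace_not_responsive():
    ep = WhiskingEpochs(epochs=[(s, s + 20) for s in range(50, 900, 100)],
                        n_frames=1000)
    res = classify_whisking_responsive(make_dff(np.zeros(1000)), ep)
    assert res.is_responsive is False and res.p_value == 1.0


def test_too_few_onsets_unclassified():
    ep = WhiskingEpochs(epochs=[(100, 120), (300, 320)], n_frames=1000)
    res = classify_whisking_responsive(make_dff(np.zeros(1000)), ep)
    assert res.is_responsive is None


def test_onset_locked_responses_flagged_and_matrix_normalised():
    from whisca import transient_kernel
    n = 3000
    onsets = list(range(100, n - 100, 140))
    ep = WhiskingEpochs(epochs=[(o, o + 25) for o in onsets], n_frames=n)
    rng = np.random.default_rng(5)
    x = rng.normal(0, 0.02, n)
    k = transient_kernel(0.18, 1.5, 10.0)
    for o in onsets:
        x[o:o + k.size] += 1.0 * k[:min(k.size, n - o)]
    res = classify_whisking_responsive(make_dff(x), ep)
    assert res.is_responsive is True
    assert res.onset_matrix.shape[0] == res.n_onsets
    # baseline-normalised: pre-onset mean of each row ~ 0
    pre = res.onset_matrix[:, res.t_axis < 0]
    assert np.abs(pre.mean(axis=1)).max() < 1e-9
    assert res.mean_onset_response > 0.3
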