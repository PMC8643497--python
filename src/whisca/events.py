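"""Calcium-transient detection, whisking-state segmentation and per-ROI
activity summaries.

Transients are maximal runs of dF/F above 3 x the noise-band SD lasting at
least 1 s.  Whisking epochs are detected from the whisker-area video
intensity by sliding-percentile detrending (50-frame window) and the same
3 x noise-band-SD threshold.  A transient is whisking-associated when its
onset falls from 1 s before a whisking onset to 2 s after the whisking
offset; everything else is spontaneous.  A neuron is whisking-responsive
when its dF/F 0.5-1.5 s after whisking onsets significantly exceeds the
0.5 s pre-onset baseline (one-sided paired test over onsets).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .processing import DffTrace, estimate_f0_and_noise, sliding_percentile

WHISKING = "whisking-associated"
SPONTANEOUS = "spontaneous"


@dataclass
class TransientEvent:
    """Supra-threshold dF/F episode; intervals are half-open frame ranges."""

    roi_id: object
    onset_frame: int
    offset_frame: int
    peak_dff: float
    peak_frame: int
    state: str | None = None

    def __post_init__(self):
        if not (self.onset_frame <= self.peak_frame < self.offset_frame):
            raise ValueError("need onset <= peak < offset")


@dataclass
class WhiskingEpochs:
    """Sorted, non-overlapping half-open whisking intervals."""

    epochs: list               # list of (start_frame, end_frame)
    n_frames: int
    detect_params: dict = field(default_factory=dict)

    def __post_init__(self):
        prev_end = -1
        for s, e in self.epochs:
            if s >= e or s <= prev_end:
                raise ValueError("epochs must be sorted and non-overlapping")
            prev_end = e

    def mask(self) -> np.ndarray:
        m = np.zeros(self.n_frames, dtype=bool)
        for s, e in self.epochs:
            m[s:e] = True
        return m

    def onsets(self) -> np.ndarray:
        return np.array([s for s, _ in self.epochs], dtype=int)


@dataclass
class ActivitySummary:
    """Per-ROI activity metrics split by behavioural state."""

    roi_id: object
    freq_stationary: float     # events/min
    freq_whisking: float       # events/min
    amp_stationary: float      # mean peak dF/F of spontaneous transients
    amp_whisking: float
    is_active: bool
    angle_deg: float           # atan2(freq_whisking, freq_stationary), degrees
    n_events: int
    is_whisking_responsive: bool | None = None
    mean_onset_response: float = np.nan
    responsive_p: float = np.nan


def _runs(mask: np.ndarray):
    """(start, end) half-open intervals of maximal True runs."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    d = np.diff(m.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(m.size)
    return list(zip(starts, ends))


def detect_transients(dff: DffTrace, threshold_sd: float = 3.0,
                      min_duration_frames: int = 10) -> list:
    """Maximal runs of dF/F above ``threshold_sd x noise_sd`` lasting at
    least ``min_duration_frames`` frames.  An ROI with >= 1 event is active."""
    x = np.asarray(dff.dff, dtype=float)
    if dff.noise_sd == 0:
        if np.ptp(x) > 0:
            raise RuntimeError(
                "noise_sd is zero for a non-constant trace; the trace was not "
                "processed through the noise-band pipeline")
        return []
    thr = threshold_sd * dff.noise_sd
    events = []
    for s, e in _runs(x > thr):
        if e - s < min_duration_frames:
            continue
        peak = s + int(np.argmax(x[s:e]))
        events.append(TransientEvent(roi_id=dff.roi_id, onset_frame=s,
                                     offset_frame=e, peak_dff=float(x[peak]),
                                     peak_frame=peak))
    return events


def detect_whisking_epochs(behavior_trace: np.ndarray, frame_rate_hz: float,
                           window_frames: int = 50, threshold_sd: float = 3.0,
                           merge_gap_frames: int = 5,
                           min_epoch_frames: int = 3) -> WhiskingEpochs:
    """Segment whisking epochs from the whisker-ROI intensity trace.

    The trace is detrended by a sliding 8th percentile (50-frame window);
    frames exceeding 3 x the noise-band SD are whisking.  Epochs separated by
    fewer than ``merge_gap_frames`` frames are merged, then epochs shorter
    than ``min_epoch_frames`` are dropped.
    """
    x = np.asarray(behavior_trace, dtype=float)
    d = x - sliding_percentile(x, window_frames, 8.0)
    # the 8th-percentile subtraction leaves a positive offset, so the
    # threshold is referenced to the noise band's own baseline (median of
    # sub-70th-percentile samples, the F0 construction)
    base, noise_sd, _ = estimate_f0_and_noise(d, frame_rate_hz)
    if noise_sd == 0:
        epochs = []
    else:
        active = d > base + threshold_sd * noise_sd
        epochs = _runs(active)
        # merge epochs separated by short gaps
        merged = []
        for s, e in epochs:
            if merged and s - merged[-1][1] < merge_gap_frames:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        epochs = [(s, e) for s, e in merged if e - s >= min_epoch_frames]
    return WhiskingEpochs(epochs=epochs, n_frames=x.size,
                          detect_params=dict(window_frames=window_frames,
                                             threshold_sd=threshold_sd,
                                             merge_gap_frames=merge_gap_frames,
                                             min_epoch_frames=min_epoch_frames))


def whisking_association_mask(epochs: WhiskingEpochs, frame_rate_hz: float,
                              pre_s: float = 1.0, post_s: float = 2.0) -> np.ndarray:
    """Frames counted as whisking-associated: each epoch extended by the
    pre-onset and post-offset margins, clipped to the recording."""
    n = epochs.n_frames
    pre = int(round(pre_s * frame_rate_hz))
    post = int(round(post_s * frame_rate_hz))
    m = np.zeros(n, dtype=bool)
    for s, e in epochs.epochs:
        m[max(0, s - pre):min(n, e + post)] = True
    return m


def label_transient_states(events: list, epochs: WhiskingEpochs,
                           frame_rate_hz: float, pre_s: float = 1.0,
                           post_s: float = 2.0) -> list:
    """Label each event whisking-associated iff its onset lies in any
    ``[epoch_start - pre, epoch_end + post)`` window (closed lower bound);
    all other events are spontaneous.  Labels in place; returns the list."""
    mask = whisking_association_mask(epochs, frame_rate_hz, pre_s, post_s)
    for ev in events:
        ev.state = WHISKING if mask[ev.onset_frame] else SPONTANEOUS
    return events


def summarize_activity(events: list, epochs: WhiskingEpochs, dff: DffTrace,
                       pre_s: float = 1.0, post_s: float = 2.0) -> ActivitySummary:
    """Per-state transient frequency (events/min), mean amplitude and the
    activity angle ``atan2(freq_whisking, freq_stationary)`` in degrees
    (0 deg = exclusively stationary activity, 90 deg = exclusively
    whisking-associated)."""
    fps = dff.frame_rate_hz
    n = len(dff.dff)
    if any(ev.state is None for ev in events):
        events = label_transient_states(events, epochs, fps, pre_s, post_s)
    mask = whisking_association_mask(epochs, fps, pre_s, post_s)
    t_whisk_min = mask.sum() / fps / 60.0
    t_stat_min = (n - mask.sum()) / fps / 60.0
    n_w = sum(ev.state == WHISKING for ev in events)
    n_s = sum(ev.state == SPONTANEOUS for ev in events)
    freq_w = n_w / t_whisk_min if t_whisk_min > 0 else np.nan
    freq_s = n_s / t_stat_min if t_stat_min > 0 else np.nan
    amps_w = [ev.peak_dff for ev in events if ev.state == WHISKING]
    amps_s = [ev.peak_dff for ev in events if ev.state == SPONTANEOUS]
    if np.isfinite(freq_w) and np.isfinite(freq_s) and (freq_w + freq_s) > 0:
        angle = float(np.degrees(np.arctan2(freq_w, freq_s)))
    else:
        angle = np.nan
    return ActivitySummary(roi_id=dff.roi_id,
                           freq_stationary=freq_s, freq_whisking=freq_w,
                           amp_stationary=float(np.mean(amps_s)) if amps_s else np.nan,
                           amp_whisking=float(np.mean(amps_w)) if amps_w else np.nan,
                           is_active=len(events) > 0, angle_deg=angle,
                           n_events=len(events))


@dataclass
class WhiskingResponse:
    """Outcome of the whisking-responsiveness test for one ROI."""

    is_responsive: bool | None      # None = unclassified (too few onsets)
    p_value: float
    n_onsets: int
    onset_matrix: np.ndarray | None  # onsets x frames, baseline-subtracted
    t_axis: np.ndarray | None        # seconds relative to whisking onset
    mean_onset_response: float


def classify_whisking_responsive(dff: DffTrace, epochs: WhiskingEpochs,
                                 response_window_s=(0.5, 1.5),
                                 baseline_window_s: float = 0.5,
                                 alpha: float = 0.05, min_onsets: int = 5,
                                 test: str = "wilcoxon",
                                 segment_post_s: float = 2.0) -> WhiskingResponse:
    """Test for a significant dF/F increase after whisking onsets.

    Per onset: response = mean dF/F in ``(onset + 0.5 s, onset + 1.5 s]``,
    baseline = mean dF/F in ``[onset - 0.5 s, onset)``.  A one-sided paired
    Wilcoxon signed-rank test (or paired t-test) over onsets at level
    ``alpha`` decides the flag.  Onsets closer than 2 s to the recording
    start, or without a complete response window, are excluded.  Fewer than
    ``min_onsets`` usable onsets leaves the ROI unclassified.

    The onset-aligned matrix holds each onset's dF/F segment (from
    ``-baseline_window_s`` to ``+segment_post_s``) normalised by subtracting
    its pre-onset baseline mean.
    """
    fps = dff.frame_rate_hz
    x = np.asarray(dff.dff, dtype=float)
    n = x.size
    r0 = int(round(response_window_s[0] * fps))
    r1 = int(round(response_window_s[1] * fps))
    b = int(round(baseline_window_s * fps))
    seg_post = int(round(segment_post_s * fps))
    min_start = int(round(2.0 * fps))

    baselines, responses, segments = [], [], []
    for on in epochs.onsets():
        if on < max(min_start, b) or on + r1 >= n:
            continue
        base = x[on - b:on].mean()
        resp = x[on + r0 + 1:on + r1 + 1].mean()
        baselines.append(base)
        responses.append(resp)
        hi = min(n, on + seg_post)
        seg = np.full(b + seg_post, np.nan)
        seg[:b + hi - on] = x[on - b:hi] - base
        segments.append(seg)
    n_onsets = len(responses)
    if n_onsets < min_onsets:
        return WhiskingResponse(is_responsive=None, p_value=np.nan,
                                n_onsets=n_onsets, onset_matrix=None,
                                t_axis=None, mean_onset_response=np.nan)
    responses = np.array(responses)
    baselines = np.array(baselines)
    diffs = responses - baselines
    if np.allclose(diffs, 0):
        p = 1.0
    elif test == "wilcoxon":
        p = float(stats.wilcoxon(responses, baselines,
                                 alternative="greater").pvalue)
    elif test == "ttest":
        p = float(stats.ttest_rel(responses, baselines,
                                  alternative="greater").pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    matrix = np.vstack(segments)
    t_axis = (np.arange(b + seg_post) - b) / fps
    mean_resp = float(np.mean(diffs))
    return WhiskingResponse(is_responsive=bool(p < alpha), p_value=p,
                            n_onsets=n_onsets, onset_matrix=matrix,
                            t_axis=t_axis, mean_onset_response=mean_resp)
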