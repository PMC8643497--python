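"""End-to-end analysis of one simulated experiment (field of view).

Glue that chains the modules in the standard order — simulate (or load)
traces, neuropil correction, dF/F, transient and whisking detection, state
labelling, per-ROI summaries, responsiveness, and state-restricted pairwise
correlations — and collects everything into tabular form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import SimulationConfig, simulate_behavior, simulate_traces
from .io import RawTraceSet
from .processing import process_raw
from .events import (detect_transients, detect_whisking_epochs,
                     label_transient_states, summarize_activity,
                     classify_whisking_responsive, whisking_association_mask)
from .correlations import prepare_correlation_traces, pairwise_correlations


@dataclass
class ExperimentResult:
    """Per-ROI table plus experiment-level correlation summaries."""

    roi_table: pd.DataFrame
    events: list
    epochs: object
    ground_truth: object
    mean_r_stationary: float
    mean_r_whisking: float
    median_r_stationary: float
    median_r_whisking: float
    corr_stationary: object = None
    corr_whisking: object = None

    @property
    def responsive_fraction_all(self) -> float:
        flags = self.roi_table["is_whisking_responsive"]
        return float((flags == True).sum() / len(flags))  # noqa: E712

    @property
    def responsive_fraction_classified(self) -> float:
        flags = self.roi_table["is_whisking_responsive"].dropna()
        if len(flags) == 0:
            return np.nan
        return float(flags.astype(bool).mean())


def analyze_experiment(raw: RawTraceSet, behavior: np.ndarray,
                       neuropil_r: float = 0.7,
                       stationary_exclusion_post_s: float = 8.0) -> ExperimentResult:
    """Run the full analysis on raw traces plus a behaviour trace.

    Stationary-state correlations are computed on frames at least
    ``stationary_exclusion_post_s`` after the last whisking offset: a
    whisking-driven transient outlasts the 2-s labelling margin (seconds-long
    decay plus the 25-frame correlation smoothing), and without the longer
    exclusion its tail would leak whisking synchrony into the quiescent
    estimate.
    """
    fps = raw.frame_rate_hz
    dffs = process_raw(raw, neuropil_r=neuropil_r)
    epochs = detect_whisking_epochs(behavior, fps)
    assoc = whisking_association_mask(epochs, fps)
    assoc_wide = whisking_association_mask(
        epochs, fps, post_s=stationary_exclusion_post_s)

    all_events, rows = [], []
    responses = []
    for d in dffs:
        ev = detect_transients(d) if d.valid else []
        label_transient_states(ev, epochs, fps)
        summ = summarize_activity(ev, epochs, d)
        resp = classify_whisking_responsive(d, epochs) if d.valid else None
        if resp is not None:
            summ.is_whisking_responsive = resp.is_responsive
            summ.mean_onset_response = resp.mean_onset_response
            summ.responsive_p = resp.p_value
        all_events.extend(ev)
        responses.append(resp)
        rows.append(dict(roi_id=d.roi_id, valid=d.valid, f0=d.f0,
                         noise_sd=d.noise_sd, is_active=summ.is_active,
                         n_events=summ.n_events,
                         freq_stationary=summ.freq_stationary,
                         freq_whisking=summ.freq_whisking,
                         freq_total=(summ.n_events
                                     / (len(d.dff) / fps / 60.0)),
                         amp_stationary=summ.amp_stationary,
                         amp_whisking=summ.amp_whisking,
                         amp_mean=np.nanmean([summ.amp_stationary,
                                              summ.amp_whisking]),
                         angle_deg=summ.angle_deg,
                         is_whisking_responsive=summ.is_whisking_responsive,
                         mean_onset_response=summ.mean_onset_response))
    table = pd.DataFrame(rows)

    active_idx = [i for i, d in enumerate(dffs)
                  if d.valid and table["is_active"].iloc[i]]
    corr_s = corr_w = None
    if len(active_idx) >= 2:
        gated = prepare_correlation_traces([dffs[i] for i in active_idx])
        ids = [dffs[i].roi_id for i in active_idx]
        corr_w = pairwise_correlations(gated, assoc, roi_ids=ids)
        corr_s = pairwise_correlations(gated, ~assoc_wide, roi_ids=ids)

    def _mm(c):
        if c is None or c.defined.size == 0:
            return np.nan, np.nan
        return float(c.defined.mean()), float(np.median(c.defined))

    mean_s, med_s = _mm(corr_s)
    mean_w, med_w = _mm(corr_w)
    return ExperimentResult(roi_table=table, events=all_events, epochs=epochs,
                            ground_truth=None,
                            mean_r_stationary=mean_s, mean_r_whisking=mean_w,
                            median_r_stationary=med_s, median_r_whisking=med_w,
                            corr_stationary=corr_s, corr_whisking=corr_w)


def run_experiment(config: SimulationConfig, seed: int | None = None) -> ExperimentResult:
    """Simulate one field of view and analyse it end to end."""
    seed = config.seed if seed is None else seed
    raw_traces, npil_traces, gt = simulate_traces(config, seed)
    behavior, _ = simulate_behavior(config, seed)
    raw = RawTraceSet(traces=raw_traces, neuropil_traces=npil_traces,
                      frame_rate_hz=config.frame_rate_hz,
                      roi_ids=list(range(config.n_rois)))
    result = analyze_experiment(raw, behavior,
                                neuropil_r=config.neuropil_ratio)
    result.ground_truth = gt
    return result


def events_table(events: list) -> pd.DataFrame:
    """Events as one row per transient."""
    return pd.DataFrame([dict(roi_id=ev.roi_id, onset_frame=ev.onset_frame,
                              offset_frame=ev.offset_frame,
                              peak_frame=ev.peak_frame, peak_dff=ev.peak_dff,
                              state=ev.state) for ev in events])


def epochs_table(epochs) -> pd.DataFrame:
    return pd.DataFrame([dict(start_frame=s, end_frame=e)
                         for s, e in epochs.epochs])
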