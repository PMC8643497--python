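"""Raw fluorescence to dF/F with an explicit noise-band model.

The processing chain is: low-pass smoothing, removal of slow fluctuations by
subtracting a sliding 8th-percentile baseline (1000-frame window), then F0
and noise estimation from the "noise band" — the residual after subtracting a
1-s sliding 8th percentile.  F0 is the median of samples whose noise-band
value lies below the noise band's 70th percentile; the SD of those same
sub-70th-percentile noise-band samples is the noise SD that every downstream
3 x SD threshold refers to.  The module is fully deterministic.

Sliding windows are centred and truncated at the edges (no padding), and
percentiles use linear interpolation between order statistics.  The pipeline
adds the global median of the slow baseline back after detrending, so F0
keeps the absolute fluorescence level that dF/F divides by while the slow
fluctuations themselves are removed; a constant trace therefore maps to
dF/F identically zero, and scaling a trace by c > 0 leaves dF/F unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.stats import norm

logger = logging.getLogger(__name__)


@dataclass
class DffTrace:
    """Processed per-ROI dF/F trace with its baseline and noise model."""

    dff: np.ndarray
    f0: float
    noise_sd: float            # dF/F units
    frame_rate_hz: float
    params: dict = field(default_factory=dict)
    roi_id: object = None
    valid: bool = True

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def sliding_percentile(x: np.ndarray, window_frames: int, percentile: float) -> np.ndarray:
    """Centred sliding percentile with truncated edge windows.

    The window at frame t covers ``[t - w//2, t + w - w//2)`` clipped to the
    trace; percentiles interpolate linearly between order statistics.  If the
    window exceeds the trace length, the global percentile is returned for
    every frame (with a warning).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    w = int(window_frames)
    if w < 3:
        raise ValueError("window_frames must be >= 3")
    if not (0 < percentile < 100):
        raise ValueError("percentile must be in (0, 100)")
    if w > n:
        warnings.warn("window longer than trace: falling back to the global "
                      "percentile")
        return np.full(n, np.percentile(x, percentile))
    half_lo = w // 2
    half_hi = w - half_lo
    out = np.empty(n)
    # full windows, vectorised via partition (linear interpolation as np.percentile)
    views = np.lib.stride_tricks.sliding_window_view(x, w)
    pos = percentile / 100.0 * (w - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, w - 1)
    part = np.partition(views, (lo, hi), axis=-1)
    vals = part[:, lo] + (pos - lo) * (part[:, hi] - part[:, lo])
    out[half_lo:n - half_hi + 1] = vals
    # truncated edges
    for t in range(half_lo):
        out[t] = np.percentile(x[:t + half_hi], percentile)
    for t in range(n - half_hi + 1, n):
        out[t] = np.percentile(x[t - half_lo:], percentile)
    return out


def lowpass_filter(trace: np.ndarray, cutoff_hz: float,
                   frame_rate_hz: float) -> np.ndarray:
    """Zero-phase low-pass smoothing with unit DC gain.

    At a cutoff equal to the Nyquist frequency an ideal filter is the
    identity, so the cutoff-at-Nyquist case is implemented as a 3-frame
    binomial smoothing kernel (attenuating the Nyquist alternation itself);
    lower cutoffs use a zero-phase 2nd-order Butterworth filter.
    """
    trace = np.asarray(trace, dtype=float)
    nyq = frame_rate_hz / 2.0
    if cutoff_hz <= 0 or cutoff_hz > nyq:
        raise ValueError(f"cutoff must be in (0, {nyq}] Hz")
    if cutoff_hz >= 0.99 * nyq:
        p = np.pad(trace, 1, mode="reflect")
        return 0.25 * p[:-2] + 0.5 * p[1:-1] + 0.25 * p[2:]
    b, a = sps.butter(2, cutoff_hz / nyq)
    padlen = min(3 * max(len(a), len(b)), trace.size - 1)
    return sps.filtfilt(b, a, trace, padlen=padlen)


def detrend(trace: np.ndarray, window_frames: int = 1000,
            percentile: float = 8.0) -> np.ndarray:
    """Remove slow fluctuations by subtracting a sliding percentile baseline."""
    trace = np.asarray(trace, dtype=float)
    return trace - sliding_percentile(trace, window_frames, percentile)


def truncation_correction(percentile: float) -> float:
    """Factor restoring a Gaussian SD from the SD of samples below the given
    percentile (the analogue of the 1.4826 in MAD-based scale estimates).

    For X ~ N(0, 1) truncated at its p-th percentile z, ``Var(X | X < z) =
    1 - z phi(z)/Phi(z) - (phi(z)/Phi(z))^2``; the correction is the inverse
    square root of that.
    """
    q = percentile / 100.0
    z = norm.ppf(q)
    ratio = norm.pdf(z) / q
    var = 1.0 - z * ratio - ratio ** 2
    return 1.0 / float(np.sqrt(var))


def estimate_f0_and_noise(trace: np.ndarray, frame_rate_hz: float,
                          f0_window_s: float = 1.0,
                          noise_percentile: float = 70.0,
                          baseline_percentile: float = 8.0):
    """Estimate baseline fluorescence F0 and the noise-band SD.

    ``noise_band(t) = trace(t) - P8(1-s centred window)``;
    ``F0 = median{trace(t) : noise_band(t) < P70(noise_band)}``;
    ``noise_sd = SD{noise_band(t) : noise_band(t) < P70(noise_band)}``
    rescaled by the Gaussian truncation correction, so it estimates the full
    noise-band SD while staying robust to transients (which concentrate in
    the excluded supra-70th-percentile samples).  Returns
    ``(f0, noise_sd, noise_band)``.
    """
    trace = np.asarray(trace, dtype=float)
    w = max(3, int(round(f0_window_s * frame_rate_hz)))
    noise_band = trace - sliding_percentile(trace, w, baseline_percentile)
    p = np.percentile(noise_band, noise_percentile)
    sel = noise_band < p
    if not sel.any():            # degenerate (e.g. constant) trace
        sel = np.ones(trace.size, dtype=bool)
    f0 = float(np.median(trace[sel]))
    noise_sd = float(noise_band[sel].std()
                     * truncation_correction(noise_percentile))
    return f0, noise_sd, noise_band


def compute_dff(trace: np.ndarray, frame_rate_hz: float,
                lowpass_hz: float | None = 5.0,
                detrend_window_frames: int = 1000,
                detrend_percentile: float = 8.0,
                f0_window_s: float = 1.0,
                noise_percentile: float = 70.0,
                roi_id=None) -> DffTrace:
    """Full raw-trace to dF/F pipeline for one ROI.

    Low-pass, subtract the sliding 8th-percentile slow baseline while adding
    its global median back (slow fluctuations removed, absolute baseline
    level preserved), then estimate F0 and the noise-band SD and divide:
    ``dff = (detrended - F0) / F0``.  An ROI whose F0 is non-positive cannot
    be normalised and is returned flagged ``valid=False`` with a zero trace.
    """
    trace = np.asarray(trace, dtype=float)
    f = lowpass_filter(trace, lowpass_hz, frame_rate_hz) if lowpass_hz else trace
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short-trace fallback is intended here
        slow = sliding_percentile(f, detrend_window_frames, detrend_percentile)
    level = float(np.median(slow))
    d = f - slow + level
    f0, noise_sd_f, _ = estimate_f0_and_noise(
        d, frame_rate_hz, f0_window_s=f0_window_s,
        noise_percentile=noise_percentile,
        baseline_percentile=detrend_percentile)
    params = dict(lowpass_hz=lowpass_hz,
                  detrend_window_frames=detrend_window_frames,
                  detrend_percentile=detrend_percentile,
                  f0_window_s=f0_window_s, noise_percentile=noise_percentile)
    if f0 <= 0:
        logger.warning("ROI %s: non-positive F0 (%.3g), flagged unusable",
                       roi_id, f0)
        return DffTrace(dff=np.zeros_like(d), f0=f0, noise_sd=0.0,
                        frame_rate_hz=frame_rate_hz, params=params,
                        roi_id=roi_id, valid=False)
    return DffTrace(dff=(d - f0) / f0, f0=f0, noise_sd=noise_sd_f / f0,
                    frame_rate_hz=frame_rate_hz, params=params, roi_id=roi_id)


def process_raw(raw, neuropil_r: float = 0.7, **dff_kwargs) -> list:
    """Neuropil-correct a :class:`~whisca.io.RawTraceSet` and compute dF/F
    for every ROI.  Returns a list of :class:`DffTrace`."""
    from .io import neuropil_correct
    corrected = neuropil_correct(raw, r=neuropil_r)
    ids = corrected.roi_ids or list(range(corrected.traces.shape[0]))
    return [compute_dff(corrected.traces[i], corrected.frame_rate_hz,
                        roi_id=ids[i], **dff_kwargs)
            for i in range(corrected.traces.shape[0])]
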