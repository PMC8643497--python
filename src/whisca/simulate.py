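"""Synthetic two-photon calcium imaging data with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: GCaMP6s-like transients (fast rise, seconds-long decay) riding on a
noisy, slowly drifting baseline with neuropil contamination; a two-state
whisking/stationary behaviour process; state-dependent event rates with an
optional population-shared drive during whisking (creating pairwise
correlations); and optionally a rendered two-channel movie with rigid motion
for registration testing.  Every draw is reproducible from a single seed via
a documented stream-splitting scheme.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import TwoChannelMovie

# Sub-stream identifiers: all randomness flows from SeedSequence([seed, k]).
STREAM_BEHAVIOR = 0
STREAM_EVENTS = 1
STREAM_NOISE = 2
STREAM_MOVIE = 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    if seed < 0:
        raise ValueError("seed must be non-negative")
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic recording.

    Defaults describe the control-like condition: sparse activity in layer-2/3
    somatosensory cortex at a 10 Hz frame rate, with a subset of ROIs whose
    event rate is elevated during whisking.
    """

    n_rois: int = 40
    duration_s: float = 600.0
    frame_rate_hz: float = 10.0
    # per-ROI event rates (events/s); whisking rate applies to responsive ROIs
    event_rate_stationary_hz: float = 0.04
    event_rate_whisking_hz: float = 0.15
    amplitude_mean: float = 1.0      # dF/F units
    amplitude_sd: float = 0.3
    tau_rise_s: float = 0.18
    tau_decay_s: float = 1.5
    baseline_f: float = 100.0        # fluorescence units
    noise_sd: float = 2.0            # fluorescence units
    drift_amplitude: float = 4.0     # fluorescence units (SD of slow drift)
    drift_timescale_s: float = 60.0
    neuropil_ratio: float = 0.7      # mixing coefficient in [0, 1)
    whisking_mean_bout_s: float = 2.0
    whisking_mean_gap_s: float = 6.0
    shared_drive_weight: float = 0.25  # fraction of whisking events from shared train
    responsive_fraction: float = 0.2
    # responsive ROIs additionally fire time-locked to whisking onsets with
    # this per-onset probability (whisking-responsive cells respond to the
    # onset itself, not uniformly throughout the bout)
    onset_event_probability: float = 0.3
    seed: int = 0
    # behaviour-video intensity model
    behavior_baseline: float = 50.0
    behavior_whisk_amp: float = 30.0
    behavior_noise_sd: float = 2.0
    behavior_drift_amplitude: float = 3.0
    # movie rendering geometry
    fov_px: int = 64
    roi_sigma_px: float = 1.5
    func_gain: float = 0.5           # functional-channel intensity per trace unit
    anat_amplitude: float = 50.0
    movie_noise_sd: float = 1.0
    movie_background: float = 10.0
    motion_max_px: float = 0.0
    motion_subpixel: bool = False

    def validate(self) -> None:
        c = self
        if c.n_rois < 1:
            raise ValueError("n_rois must be >= 1")
        if c.duration_s <= 0 or c.frame_rate_hz <= 0:
            raise ValueError("duration_s and frame_rate_hz must be positive")
        for name in ("event_rate_stationary_hz", "event_rate_whisking_hz",
                     "amplitude_sd", "noise_sd", "drift_amplitude",
                     "behavior_noise_sd", "behavior_drift_amplitude"):
            if getattr(c, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (c.tau_decay_s > c.tau_rise_s > 0):
            raise ValueError("need tau_decay_s > tau_rise_s > 0")
        if c.amplitude_mean <= 0 or c.baseline_f <= 0:
            raise ValueError("amplitude_mean and baseline_f must be positive")
        if not (0 <= c.neuropil_ratio < 1):
            raise ValueError("neuropil_ratio must be in [0, 1)")
        if not (0 <= c.shared_drive_weight < 1):
            raise ValueError("shared_drive_weight must be in [0, 1)")
        if not (0 <= c.responsive_fraction <= 1):
            raise ValueError("responsive_fraction must be in [0, 1]")
        if not (0 <= c.onset_event_probability <= 1):
            raise ValueError("onset_event_probability must be in [0, 1]")
        if c.whisking_mean_bout_s <= 0 or c.whisking_mean_gap_s <= 0:
            raise ValueError("whisking bout/gap means must be positive")
        if max(c.event_rate_stationary_hz, c.event_rate_whisking_hz) / c.frame_rate_hz >= 1:
            raise ValueError("event rate per frame must be < 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))


def asyn_like(config: SimulationConfig) -> SimulationConfig:
    """Variant embedding the synucleinopathy-like group effects.

    Event rates x1.5, transient amplitude x1.3, responsive fraction x2 and
    whisking shared-drive weight x2 relative to the given (control) config.
    """
    return dataclasses.replace(
        config,
        event_rate_stationary_hz=1.5 * config.event_rate_stationary_hz,
        event_rate_whisking_hz=1.5 * config.event_rate_whisking_hz,
        onset_event_probability=min(1.0, 1.5 * config.onset_event_probability),
        amplitude_mean=1.3 * config.amplitude_mean,
        responsive_fraction=min(1.0, 2.0 * config.responsive_fraction),
        shared_drive_weight=min(0.99, 2.0 * config.shared_drive_weight),
    )


@dataclass
class GroundTruth:
    """True generative state of a simulated recording; oracle for recovery tests."""

    event_times: list          # per ROI, np.ndarray of event frame indices
    event_amplitudes: list     # per ROI, np.ndarray of dF/F amplitudes
    state_sequence: np.ndarray  # per frame, 1 = whisking
    kernel_params: tuple       # (tau_rise_s, tau_decay_s)
    responsive_mask: np.ndarray
    applied_shifts: np.ndarray | None = None  # (n_frames, 2) (dy, dx)
    roi_centroids: np.ndarray | None = None   # (n_rois, 2) (y, x)


def _smooth_drift(rng: np.random.Generator, n: int, sigma_frames: float,
                  amplitude: float) -> np.ndarray:
    """Slow random fluctuation: white noise smoothed to the drift timescale,
    rescaled to the requested SD."""
    w = rng.standard_normal(n)
    if amplitude <= 0:
        return np.zeros(n)
    d = ndimage.gaussian_filter1d(w, max(sigma_frames, 1.0), mode="reflect")
    sd = d.std()
    return d * (amplitude / sd) if sd > 0 else np.zeros(n)


def transient_kernel(tau_rise_s: float, tau_decay_s: float,
                     frame_rate_hz: float) -> np.ndarray:
    """Difference-of-exponentials calcium response kernel, sampled at the
    frame rate and normalised so its sampled peak equals 1."""
    if not (tau_decay_s > tau_rise_s > 0):
        raise ValueError("need tau_decay_s > tau_rise_s > 0")
    t = np.arange(0.0, 8.0 * tau_decay_s, 1.0 / frame_rate_hz)
    h = np.exp(-t / tau_decay_s) - np.exp(-t / tau_rise_s)
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate kernel")
    return h / peak


def _simulate_state(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Alternating exponential renewal process rasterised to frames."""
    n = config.n_frames
    fps = config.frame_rate_hz
    state = np.zeros(n, dtype=np.int8)
    t = rng.exponential(config.whisking_mean_gap_s)  # recording starts stationary
    while t < config.duration_s:
        bout = rng.exponential(config.whisking_mean_bout_s)
        s = int(np.ceil(t * fps))
        e = int(np.ceil((t + bout) * fps))
        state[s:min(e, n)] = 1
        t += bout + rng.exponential(config.whisking_mean_gap_s)
    return state


def simulate_behavior(config: SimulationConfig, seed: int | None = None):
    """Simulate the whisker-area video intensity trace.

    Returns ``(behavior_intensity, state_sequence)``: the binary state from an
    alternating exponential renewal process, and a continuous trace that is
    elevated and fluctuating during whisking, baseline plus noise plus slow
    drift otherwise.  Deterministic given (config, seed); the state sequence
    is identical to the one used by :func:`simulate_traces` for the same seed.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = _rng(seed, STREAM_BEHAVIOR)
    n = config.n_frames
    state = _simulate_state(config, rng)
    drift = _smooth_drift(rng, n, config.drift_timescale_s * config.frame_rate_hz,
                          config.behavior_drift_amplitude)
    # strong within-bout variability: video motion energy oscillates with the
    # aliased whisker sweeps rather than holding a sustained plateau, which is
    # what keeps a sliding low-percentile baseline anchored during long bouts
    fluct = 0.3 + 0.7 * rng.random(n)
    noise = rng.normal(0.0, config.behavior_noise_sd, n) if config.behavior_noise_sd > 0 else 0.0
    intensity = (config.behavior_baseline + drift
                 + config.behavior_whisk_amp * state * fluct + noise)
    return intensity, state


def simulate_traces(config: SimulationConfig, seed: int | None = None,
                    event_times: list | None = None,
                    event_amplitudes: list | None = None):
    """Simulate raw ROI and neuropil fluorescence traces.

    Events are drawn per frame from a state-dependent Bernoulli approximation
    of an inhomogeneous Poisson process.  Responsive ROIs fire at
    ``event_rate_whisking_hz`` during whisking; a fraction
    ``shared_drive_weight`` of each ROI's whisking-state events is adopted
    from a population-shared latent train (substituting for, not adding to,
    independent events, so the marginal rate is conserved).  Each event is
    convolved with a peak-normalised difference-of-exponentials kernel and
    scaled by a positive amplitude; white noise, slow drift and a neuropil
    trace (mixed with coefficient ``neuropil_ratio``) complete the raw trace.

    ``event_times`` / ``event_amplitudes`` may be supplied (per-ROI arrays) to
    bypass the stochastic event draw while keeping the same trace model.

    Returns ``(raw_traces, neuropil_traces, GroundTruth)`` with shapes
    ``(n_rois, n_frames)``.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    n = config.n_frames
    fps = config.frame_rate_hz
    n_rois = config.n_rois

    state = _simulate_state(config, _rng(seed, STREAM_BEHAVIOR))
    whisk = state == 1

    rng_e = _rng(seed, STREAM_EVENTS)
    rng_n = _rng(seed, STREAM_NOISE)

    kernel = transient_kernel(config.tau_rise_s, config.tau_decay_s, fps)
    p_w = config.event_rate_whisking_hz / fps
    p_s = config.event_rate_stationary_hz / fps
    w = config.shared_drive_weight

    n_resp = int(round(config.responsive_fraction * n_rois))
    responsive = np.zeros(n_rois, dtype=bool)
    if n_resp > 0:
        responsive[rng_e.choice(n_rois, size=n_resp, replace=False)] = True

    # population-shared latent event train, active only during whisking
    shared = whisk & (rng_e.random(n) < p_w) if p_w > 0 else np.zeros(n, dtype=bool)
    bout_onsets = np.flatnonzero(np.diff(state.astype(np.int8)) == 1) + 1

    ev_times, ev_amps = [], []
    signal = np.zeros((n_rois, n))
    for i in range(n_rois):
        if event_times is not None:
            frames = np.asarray(event_times[i], dtype=int)
            if frames.size and (frames.min() < 0 or frames.max() >= n):
                raise ValueError("event_times out of range")
        else:
            # per-frame event probability for this ROI
            p_frame = np.where(whisk, p_w if responsive[i] else p_s, p_s)
            ev = np.zeros(n, dtype=bool)
            if w > 0 and p_w > 0:
                adopt = w * p_frame / p_w  # thinning keeps the marginal rate
                ev |= shared & (rng_e.random(n) < adopt)
                p_indep = np.where(whisk, (1.0 - w) * p_frame, p_frame)
            else:
                p_indep = p_frame
            ev |= rng_e.random(n) < p_indep
            if responsive[i] and config.onset_event_probability > 0:
                locked = bout_onsets[rng_e.random(bout_onsets.size)
                                     < config.onset_event_probability]
                ev[locked] = True
            frames = np.flatnonzero(ev)
        if event_amplitudes is not None:
            amps = np.asarray(event_amplitudes[i], dtype=float)
            if amps.size != frames.size:
                raise ValueError("event_amplitudes must match event_times in length")
        else:
            amps = rng_e.normal(config.amplitude_mean, config.amplitude_sd, frames.size)
            amps = np.clip(amps, 0.05 * config.amplitude_mean, None)
        ev_times.append(frames)
        ev_amps.append(amps)
        train = np.zeros(n)
        np.add.at(train, frames, amps)
        signal[i] = np.convolve(train, kernel)[:n]

    mean_signal = signal.mean(axis=0)
    npil_common = (_smooth_drift(rng_n, n, config.drift_timescale_s * fps,
                                 config.drift_amplitude)
                   + 0.15 * config.baseline_f * mean_signal)

    raw = np.empty((n_rois, n))
    npil = np.empty((n_rois, n))
    for i in range(n_rois):
        clean = config.baseline_f * (1.0 + signal[i])
        drift = _smooth_drift(rng_n, n, config.drift_timescale_s * fps,
                              config.drift_amplitude)
        noise = rng_n.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else 0.0
        npil_noise = (rng_n.normal(0.0, 0.5 * config.noise_sd, n)
                      if config.noise_sd > 0 else 0.0)
        npil_fluct = npil_common + npil_noise
        npil[i] = 0.7 * config.baseline_f + npil_fluct
        contamination = config.neuropil_ratio * (npil[i] - np.median(npil[i]))
        raw[i] = clean + drift + noise + contamination

    gt = GroundTruth(event_times=ev_times, event_amplitudes=ev_amps,
                     state_sequence=state,
                     kernel_params=(config.tau_rise_s, config.tau_decay_s),
                     responsive_mask=responsive)
    return raw, npil, gt


def _place_centroids(rng: np.random.Generator, n_rois: int, fov: int,
                     margin: float, min_sep: float) -> np.ndarray:
    centroids = []
    tries = 0
    while len(centroids) < n_rois:
        tries += 1
        if tries > 500 * n_rois:
            raise RuntimeError(
                f"could not place {n_rois} non-overlapping ROIs in a "
                f"{fov}x{fov} field")
        c = margin + rng.random(2) * (fov - 2 * margin)
        if all(np.hypot(c[0] - p[0], c[1] - p[1]) >= min_sep for p in centroids):
            centroids.append(c)
    return np.array(centroids)


def render_movie(traces: np.ndarray, config: SimulationConfig,
                 seed: int | None = None, shifts: np.ndarray | None = None,
                 ground_truth: GroundTruth | None = None):
    """Render raw traces into a two-channel movie with optional rigid motion.

    ROIs become 2-D Gaussian spots at random non-overlapping centroids.  The
    functional channel follows each ROI's trace; the anatomical channel is a
    static spot image.  Per-frame rigid shifts (``shifts`` or drawn up to
    ``config.motion_max_px``) are applied identically to both channels and
    recorded in ``GroundTruth.applied_shifts`` (displacement of the frame
    content relative to the unshifted scene, (dy, dx)).
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = _rng(seed, STREAM_MOVIE)
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    n_rois, n_frames = traces.shape
    fov = config.fov_px
    sigma = config.roi_sigma_px
    margin = 3.0 * sigma + abs(config.motion_max_px) + 1.0
    if 2 * margin >= fov:
        raise RuntimeError("field of view too small for ROI geometry")
    centroids = _place_centroids(rng, n_rois, fov, margin, 5.0 * sigma)

    yy, xx = np.mgrid[0:fov, 0:fov]
    spots = np.stack([
        np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma ** 2))
        for cy, cx in centroids
    ])  # (n_rois, fov, fov), peak 1 per spot

    anat_scene = config.movie_background + config.anat_amplitude * spots.sum(axis=0)

    if shifts is None:
        if config.motion_max_px > 0:
            m = config.motion_max_px
            if config.motion_subpixel:
                shifts = rng.uniform(-m, m, size=(n_frames, 2))
            else:
                shifts = rng.integers(-int(m), int(m) + 1,
                                      size=(n_frames, 2)).astype(float)
            shifts[0] = 0.0
        else:
            shifts = np.zeros((n_frames, 2))
    shifts = np.asarray(shifts, dtype=float)

    func = np.empty((n_frames, fov, fov), dtype=np.float32)
    anat = np.empty((n_frames, fov, fov), dtype=np.float32)
    flat = spots.reshape(n_rois, -1)
    for f in range(n_frames):
        frame = (config.movie_background
                 + (config.func_gain * traces[:, f]) @ flat).reshape(fov, fov)
        a = anat_scene
        dy, dx = shifts[f]
        if dy != 0.0 or dx != 0.0:
            integer = float(dy).is_integer() and float(dx).is_integer()
            order = 0 if integer else 1
            frame = ndimage.shift(frame, (dy, dx), order=order,
                                  mode="constant", cval=float(np.median(frame)))
            a = ndimage.shift(a, (dy, dx), order=order,
                              mode="constant", cval=float(np.median(a)))
        if config.movie_noise_sd > 0:
            frame = frame + rng.normal(0.0, config.movie_noise_sd, (fov, fov))
            a = a + rng.normal(0.0, config.movie_noise_sd, (fov, fov))
        func[f] = frame
        anat[f] = a

    movie = TwoChannelMovie(functional=func, anatomical=anat,
                            frame_rate_hz=config.frame_rate_hz)
    if ground_truth is None:
        ground_truth = GroundTruth(event_times=[], event_amplitudes=[],
                                   state_sequence=np.zeros(n_frames, dtype=np.int8),
                                   kernel_params=(config.tau_rise_s, config.tau_decay_s),
                                   responsive_mask=np.zeros(n_rois, dtype=bool))
    ground_truth.applied_shifts = shifts
    ground_truth.roi_centroids = centroids
    return movie, ground_truth
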