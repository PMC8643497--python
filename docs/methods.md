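# Methods

`whisca` analyses awake two-photon calcium imaging of cortical populations
recorded together with a whisker video: it turns registered two-channel
movies (or pre-extracted traces) into per-neuron ΔF/F, detects calcium
transients and whisking epochs, classifies whisking-responsive neurons,
quantifies transient kinetics, and measures state-restricted pairwise
correlations against circular-shift surrogate nulls. A synthetic-data
generator with full ground truth makes every stage verifiable.

## Signal model and processing chain

Raw ROI fluorescence is modelled as baseline + transients + slow drift +
white noise + neuropil contamination. The processing order is fixed:

1. **Neuropil correction** — `corrected = roi − r·(neuropil − median(neuropil))`
   with `r = 0.7` by default (configurable). Median-centring the annulus
   trace removes its fluctuations without destroying the absolute baseline
   that the later ΔF/F division needs.
2. **Low-pass** at 5 Hz. At the 10 Hz frame rate this cutoff equals the
   Nyquist frequency, where an ideal filter is the identity; it is therefore
   implemented as a 3-frame binomial smoothing kernel (zero-phase, DC gain 1).
   Cutoffs below Nyquist use a zero-phase 2nd-order Butterworth filter.
3. **Slow-fluctuation removal** — subtract the sliding 8th percentile in a
   1000-frame centred window, then add the global median of that baseline
   back. The add-back preserves the absolute fluorescence level: a constant
   trace maps to ΔF/F ≡ 0 exactly, and scaling a trace by c > 0 leaves ΔF/F
   unchanged (F0 scales by c). Windows are truncated at the trace edges (no
   padding); percentiles interpolate linearly between order statistics.
   Traces shorter than the window fall back to the global percentile with a
   warning.
4. **F0 and noise band** — the noise band is the residual after subtracting
   a 1-s sliding 8th percentile. F0 is the median of samples whose
   noise-band value lies below the band's 70th percentile;
   `ΔF/F = (trace − F0)/F0`. The noise SD is the SD of those same
   sub-70th-percentile band samples **rescaled by the exact Gaussian
   truncation correction** `1/sqrt(1 − z·φ(z)/Φ(z) − (φ(z)/Φ(z))²) = 1.4245`
   at P70 (the analogue of the 1.4826 in MAD-based scale estimates). Without
   the rescale the truncated SD underestimates the noise by ~30%, silently
   turning every "3 × SD" threshold into a ~2 × SD threshold.

Because F0 is a sub-percentile median, it sits ~0.5 band-SD below the noise
mean; event-free ΔF/F therefore carries a small positive offset (≈ 0.5 ×
noise SD, far below the 3 × SD detection threshold). This is a property of
the estimator, documented and tested rather than hidden. ROIs whose F0 is
non-positive cannot be normalised; they are flagged unusable and excluded
downstream with a log entry.

## Events and behavioural state

**Transients** are maximal runs of ΔF/F above 3 × noise SD lasting ≥ 10
frames (1 s); an ROI with at least one transient is *active*. Runs cannot
separate events closer than the supra-threshold duration (~2 s for a
GCaMP6s-like 1.5-s decay), so per-event times are refined by the derivative
criterion (below), which splits merged transients.

**Whisking epochs** come from the whisker-area video intensity: detrend by a
sliding 8th percentile (50-frame window), then threshold. Two
implementation details matter. First, the percentile subtraction leaves a
positive offset (≈ +1.4 σ), so the 3 × SD threshold is referenced to the
noise band's own baseline (the F0 construction applied to the behaviour
trace), not to zero. Second, epochs separated by < 5 frames are merged and
epochs shorter than 3 frames dropped (both exposed as parameters; the
merge-then-minimum order means isolated noise crossings cannot chain into
spurious epochs once the threshold is calibrated).

**State labelling**: a transient is *whisking-associated* iff its onset lies
within `[epoch_start − 1 s, epoch_end + 2 s)` (closed lower bound); all
others are *spontaneous*. The same extended windows define the
whisking-associated time base, so state frequencies (events/min) use
symmetric numerators and denominators. Events are assigned by onset only;
an event straddling a boundary is not split. The *activity angle*
`α = atan2(freq_whisking, freq_stationary)` summarises state preference:
0° = exclusively stationary activity, 90° = exclusively whisking-associated.

**Whisking responsiveness**: per whisking onset, response = mean ΔF/F in
(onset + 0.5 s, onset + 1.5 s], baseline = mean ΔF/F in [onset − 0.5 s,
onset). A one-sided paired Wilcoxon signed-rank over onsets (configurable to
a paired t-test) at α = 0.05 decides the flag; the test is unspecified in
the source procedure and Wilcoxon was chosen for robustness. ROIs with
fewer than 5 usable onsets (complete windows, ≥ 2 s from recording start)
stay unclassified and are excluded from responsive-fraction statistics. The
onset-aligned matrix subtracts each onset's pre-onset baseline mean.

## Transient kinetics

Onsets are found from the first derivative of the 7-frame moving-average
smoothed trace exceeding 3.5 × the derivative's baseline SD (baseline =
frames outside detected transients, a definition the source procedure
leaves open). The centred smoothing makes the smoothed trace rise half a
window early, so run starts are shifted forward by `smooth_frames // 2`.
Isolation looks forward only: an onset is isolated iff no further onset
follows within 10 s; a *preceding* event does not disqualify, but segments
whose 1-s pre-onset baseline overlaps a prior transient are dropped.
Isolated segments are aligned at onset, normalised by their 1-s pre-onset
mean, and averaged; the decay time (36.8% of peak) and half-decay time (50%)
are read off the mean transient with sub-frame linear interpolation — at
10 Hz a frame is 100 ms, too coarse otherwise.

The 36.8% decay time of a difference-of-exponentials kernel equals τ_decay
only in the fast-rise limit; with the GCaMP6s-like default rise of 0.18 s it
is 13–40% longer over τ ∈ {0.5…2.5} s. Kinetics recovery benchmarks
therefore use a fast-rise kernel (τ_rise = 0.03 s). A 0.5-s transient spans
~2 frames at 10 Hz and its sampled peak is attenuated by the low-pass, so
peak-amplitude recovery is only asserted for τ ≥ 1 s.

## Correlations and surrogate nulls

For all unordered pairs of active ROIs, traces are smoothed over 25 frames,
gated to exactly 0 below 2 × noise SD, and Pearson-correlated separately
over whisking-associated and stationary frames (the whisking mask includes
the 1 s / 2 s margins, consistent with event labelling). The stationary
mask additionally excludes 8 s after each whisking offset: a
whisking-driven transient (seconds-long decay plus the 25-frame smoothing)
outlasts the 2-s labelling margin above the gate, and without the longer
exclusion its tail would leak whisking synchrony into the quiescent
estimate. Pairs with a constant trace on the state frames are undefined
and counted; states shorter than 50 frames are skipped. The null circularly shifts each ROI's
*full-length* gated trace by an independent uniform offset in [1, length]
(length ≡ identity) before state restriction — shifting first preserves
each trace's autocorrelation and marginal distribution while destroying
cross-trace alignment. Defaults: 100 shuffles, seed logged. Note that on
traces with slow drift the null is legitimately wide (that is the point of
preserving autocorrelation); the null-validity benchmark therefore uses
drift-free, ungated, unsmoothed noise traces, for which the white-trace
sampling level (mean |R| ≈ 0.014 at 6000 frames) applies.

Group comparisons use the two-sample KS test for distributions, the
Mann-Whitney U (ranksum) for per-experiment fractions, and t-tests for
normally distributed summaries, with the effect direction reported as the
sign of the median difference; at least 3 finite values per group are
required.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
the biophysics:

- **Behaviour**: alternating exponential renewal (mean bout 2 s, mean gap
  6 s ⇒ whisking fraction 0.25 — placeholders, as no numeric bout statistics
  are available). The video-intensity trace fluctuates strongly *within*
  bouts (uniform 0.3–1.0 of the whisking amplitude per frame): motion energy
  oscillates with the aliased whisker sweeps rather than holding a plateau,
  and that structure is what keeps a sliding low-percentile baseline
  anchored during bouts longer than the detrend window.
- **Events**: per-frame Bernoulli approximation of an inhomogeneous Poisson
  process. Responsive ROIs (default fraction 0.2) fire at the whisking rate
  (0.15 Hz) during whisking and additionally fire time-locked to whisking
  onsets with probability 0.3 per onset; non-responsive ROIs keep the
  stationary rate (0.04 Hz) throughout. Onset locking reflects how
  whisking-responsive cells actually respond and is required for the
  responsive fraction to be recoverable at all. A population-shared latent
  train (whisking frames only) substitutes for a fraction
  `shared_drive_weight` of each ROI's whisking events via thinning, creating
  pairwise whisking-state correlations while conserving every marginal rate.
- **Transients**: difference-of-exponentials kernel
  `exp(−t/τ_decay) − exp(−t/τ_rise)` (defaults 1.5 s / 0.18 s,
  GCaMP6s-like), sampled at the frame rate and peak-normalised to 1 so that
  the configured amplitude (default 1.0 ± 0.3 ΔF/F, clipped positive) is the
  true sampled peak. Baseline 100 a.u., white noise 2 a.u., slow drift
  (Gaussian-smoothed noise, 60-s timescale, 4 a.u. SD).
- **Neuropil**: each ROI's annulus trace shares a slow component and 15% of
  the population-mean signal; contamination is mixed in median-centred with
  coefficient 0.7, so correction with the same r inverts it exactly.
- **Movies**: ROIs rendered as Gaussian spots at non-overlapping random
  centroids; the anatomical channel is static spots + noise; rigid shifts
  (integer or sub-pixel) are applied identically to both channels and
  recorded in the ground truth.
- **Group variant**: `asyn_like()` scales event rates ×1.5, amplitude ×1.3,
  responsive fraction ×2 and shared drive ×2 — the effect directions the
  analysis is meant to detect.

All randomness flows from a single seed through fixed sub-streams
(behaviour / events / noise / movie), so sub-results are independently
reproducible and the behaviour trace and trace simulation share one state
sequence.

What the generator does *not* emulate: spike-to-calcium biophysics
(saturation, nonlinearity), realistic optics (PSF, depth-dependent
background), bleaching, nonrigid motion, pupil/locomotion covariates, and
heavy-tailed or bursty event statistics. Passing benchmarks therefore show
the pipeline recovers the *assumed* signal structure, not that it is robust
to everything real data can do.

## Benchmark problem sizes

The recovery benchmarks use: registration 64 × 64 px, 200 frames, 10 ROIs;
event detection 50 ROIs × 6000 frames at 0.05 Hz with amplitude 5 × the
trace noise SD; whisking recovery 5 × 600-s recordings; kinetics 4 decay
constants with ~40 isolated transients each; responsiveness 200 + 50 ROIs ×
300 s; shuffle null 15 ROIs × 6000 frames × 100 shuffles; group comparison
2 groups × 8 experiments × 40 ROIs × 600 s. Recording lengths are typical
single-session durations at 10 Hz.

## Known limitations

- The 3 × SD / 10-frame run detector cannot separate transients closer than
  the supra-threshold duration; event-time recovery uses the derivative
  refinement, and frequency metrics count runs (merged bursts count once).
- The eventless ΔF/F offset (above) means event *amplitudes* are measured
  relative to a slightly conservative baseline.
- Pearson R on gated, zero-inflated traces is kept exactly as specified
  (no rank-based substitute); its null distribution on sparse traces is
  wide, which is why experiment-level summaries and surrogate nulls, not
  single pair values, are the unit of inference.
- Sub-pixel registration is estimated by upsampled cross-correlation but
  applied as integer shifts by default (exactly invertible, no interpolation
  artifacts); border pixels vacated by shifting are filled with the frame
  median, never NaN.
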