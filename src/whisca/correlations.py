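"""State-restricted pairwise correlations with circular-shift surrogate nulls
and two-sample group statistics.

Traces are smoothed over 25 frames and gated (values below 2 x the noise-band
SD set to exactly 0) before Pearson correlation.  Correlations during
whisking-associated and stationary frames are computed separately.  The null
model circularly shifts each ROI's full-length trace by an independent
uniform offset in [1, length] *before* restricting to state frames, which
preserves each trace's autocorrelation and marginal distribution while
destroying cross-trace alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class CorrelationResult:
    """Pairwise Pearson R over the frames of one behavioural state."""

    pair_ids: list                 # unordered (roi_i, roi_j) pairs
    r: np.ndarray                  # per pair; NaN where undefined
    n_frames: int                  # state frames used
    n_undefined: int
    params: dict = field(default_factory=dict)

    @property
    def defined(self) -> np.ndarray:
        return self.r[np.isfinite(self.r)]


@dataclass
class GroupComparison:
    metric_name: str
    test: str
    statistic: float
    p_value: float
    effect_direction: int          # sign of median(b) - median(a)
    n_a: int
    n_b: int


def prepare_correlation_traces(dffs: list, smooth_frames: int = 25,
                               gate_sd: float | None = 2.0) -> np.ndarray:
    """Moving-average smoothing then sub-threshold gating to exactly 0.

    ``gate_sd=None`` disables the gating (used when validating the shuffle
    null on continuous traces).  Returns an (n_rois, n_frames) matrix.
    """
    out = []
    for d in dffs:
        x = np.asarray(d.dff, dtype=float)
        if smooth_frames > 1:
            k = np.ones(smooth_frames) / smooth_frames
            pad = smooth_frames // 2
            x = np.convolve(np.pad(x, pad, mode="reflect"), k,
                            mode="valid")[:d.dff.size]
        if gate_sd is not None:
            x = np.where(x < gate_sd * d.noise_sd, 0.0, x)
        out.append(x)
    return np.vstack(out)


def _pairwise_r(sub: np.ndarray):
    """All unordered-pair Pearson R of the rows of ``sub``; constant rows
    yield NaN pairs."""
    n_rois = sub.shape[0]
    sd = sub.std(axis=1)
    const = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(sub)
    iu = np.triu_indices(n_rois, k=1)
    r = c[iu]
    bad = const[iu[0]] | const[iu[1]]
    r = np.where(bad, np.nan, r)
    pairs = list(zip(iu[0].tolist(), iu[1].tolist()))
    return pairs, r


def pairwise_correlations(traces: np.ndarray, state_mask: np.ndarray,
                          roi_ids: list | None = None,
                          min_frames: int = 50) -> CorrelationResult | None:
    """Pearson R over the masked frames for every unordered ROI pair.

    Pairs where either trace is constant on the state frames are undefined
    (NaN, counted).  A state shorter than ``min_frames`` is skipped with a
    warning (returns None).
    """
    traces = np.atleast_2d(traces)
    state_mask = np.asarray(state_mask, dtype=bool)
    if traces.shape[0] < 2:
        raise ValueError("need >= 2 ROIs for pairwise correlations")
    n_state = int(state_mask.sum())
    if n_state < min_frames:
        warnings.warn(f"state has only {n_state} frames (< {min_frames}); "
                      "skipped")
        return None
    pairs, r = _pairwise_r(traces[:, state_mask])
    if roi_ids is not None:
        pairs = [(roi_ids[i], roi_ids[j]) for i, j in pairs]
    return CorrelationResult(pair_ids=pairs, r=r, n_frames=n_state,
                             n_undefined=int(np.sum(~np.isfinite(r))),
                             params=dict(min_frames=min_frames))


def shuffled_correlations(traces: np.ndarray, state_mask: np.ndarray,
                          seed: int, n_shuffles: int = 100,
                          min_frames: int = 50) -> np.ndarray:
    """Circular-shift surrogate null distribution of pairwise R.

    For each shuffle every ROI's full-length trace is circularly shifted by
    an independent uniform offset in ``[1, n_frames]`` (a shift of exactly
    ``n_frames`` is the identity), then R is computed over the state frames.
    Returns an ``(n_shuffles, n_pairs)`` array; deterministic given ``seed``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    traces = np.atleast_2d(traces)
    state_mask = np.asarray(state_mask, dtype=bool)
    n_rois, n = traces.shape
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_shuffles):
        offsets = rng.integers(1, n + 1, size=n_rois)
        rolled = np.vstack([np.roll(traces[i], int(offsets[i]) % n)
                            for i in range(n_rois)])
        _, r = _pairwise_r(rolled[:, state_mask])
        out.append(r)
    return np.vstack(out)


def compare_groups(values_a, values_b, test: str = "ks",
                   metric_name: str = "") -> GroupComparison:
    """Two-sample comparison between groups (KS, ranksum or t-test) with the
    effect direction reported as the sign of the median difference."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 finite values")
    if test == "ks":
        res = stats.ks_2samp(a, b)
    elif test == "ranksum":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "ttest":
        res = stats.ttest_ind(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    direction = int(np.sign(np.median(b) - np.median(a)))
    return GroupComparison(metric_name=metric_name, test=test,
                           statistic=float(res.statistic),
                           p_value=float(res.pvalue),
                           effect_direction=direction,
                           n_a=a.size, n_b=b.size)
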