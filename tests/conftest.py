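import numpy as np
import pytest

from whisca import SimulationConfig, simulate_traces, simulate_behavior
from whisca.io import RawTraceSet
from whisca.processing import DffTrace, process_raw


def make_dff(trace, frame_rate_hz=10.0, noise_sd=0.1, roi_id=0, f0=1.0):
    """Wrap a ready-made dF/F array without running the percentile pipeline."""
    return DffTrace(dff=np.asarray(trace, dtype=float), f0=f0,
                    noise_sd=noise_sd, frame_rate_hz=frame_rate_hz,
                    roi_id=roi_id)


def simulate_dffs(config: SimulationConfig, seed: int):
    """Simulate and process one experiment; returns (dffs, ground_truth,
    behavior_trace)."""
    raw, npil, gt = simulate_traces(config, seed)
    behavior, _ = simulate_behavior(config, seed)
    rts = RawTraceSet(traces=raw, neuropil_traces=npil,
                      frame_rate_hz=config.frame_rate_hz,
                      roi_ids=list(range(config.n_rois)))
    dffs = process_raw(rts, neuropil_r=config.neuropil_ratio)
    return dffs, gt, behavior


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quiet_config():
    """Event-free noise-only recording."""
    return SimulationConfig(n_rois=4, duration_s=300,
                            event_rate_stationary_hz=0.0,
                            event_rate_whisking_hz=0.0,
                            responsive_fraction=0.0)
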