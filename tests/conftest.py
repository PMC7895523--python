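import numpy as np
import pytest

import trapstroke as ts


@pytest.fixture(scope="session")
def wt_recording():
    """One moderate wild-type-like recording shared by detection tests."""
    config = ts.preset_config("wt", seed=7, molecule_id="wt-shared")
    config.duration = 60.0
    trace, truth = ts.simulate_dumbbell(config)
    return config, trace, truth


@pytest.fixture(scope="session")
def wt_detection(wt_recording):
    """Covariance, peaks, and refined events for the shared recording."""
    _, trace, truth = wt_recording
    cov = ts.compute_covariance(trace, 0.030)
    peaks = ts.fit_covariance_peaks(cov)
    events = ts.refine_events(cov, peaks, ts.detect_events(cov, peaks, trace.molecule_id))
    return cov, peaks, events


def step_covariance(unbound=1.0, bound=0.2, t_on=0.5, t_off=0.7, fs=1000.0, total=1.5):
    """Ideal step covariance series: unbound level with one bound plateau."""
    n = int(total * fs)
    v = np.full(n, unbound)
    i0, i1 = int(t_on * fs), int(t_off * fs)
    v[i0:i1] = bound
    return ts.CovarianceSeries(times=np.arange(n) / fs, values=v,
                               window=0.030, sample_interval=1.0 / fs)
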