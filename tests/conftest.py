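import numpy as np
import pytest
from hypothesis import settings

import sprintavp as sp

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def profile():
    """A typical youth-athlete sprint profile."""
    return sp.derive_profile(9.0, 1.2, tc=0.15)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def _exact_trace(mss, tau, tc, rate=100.0, duration=6.0, **kwargs):
    t = np.arange(0.0, duration, 1.0 / rate)
    prof = sp.derive_profile(mss, tau, tc=tc)
    return sp.VelocityTimeTrace(t=t, v=sp.velocity_at_time(t, prof), **kwargs)


@pytest.fixture
def exact_trace_factory():
    return _exact_trace


@pytest.fixture(scope="session")
def zero_noise_study():
    """End-to-end study with every noise source off: only 20 Hz
    discretisation separates device from criterion."""
    cfg = sp.StudyConfig(
        seed=20260923,
        criterion_noise_sd=0.0,
        device_noise_sd=0.0,
        device_corr_noise_sd=0.0,
        device_accel_noise_sd=0.0,
        device_accel_corr_noise_sd=0.0,
        device_accel_gain_sd=0.0,
    )
    return sp.run_validation_study(cfg, n_resamples=0)


@pytest.fixture(scope="session")
def default_noise_reports():
    """Twenty replicate studies under the default noise model (no
    bootstrap), shared across the tests that look at their metrics."""
    out = []
    for seed in range(1, 21):
        res = sp.run_validation_study(sp.StudyConfig(seed=seed), n_resamples=0)
        out.append(
            res.report.pivot_table(
                index=["parameter", "method"], columns="metric", values="estimate"
            )
        )
    return out
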