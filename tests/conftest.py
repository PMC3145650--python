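"""Shared fixtures: the reference model, experimental statistics, and
constructed voltage traces with analytically known spike geometry."""

import numpy as np
import pytest

from dendrofit.cablesim import Trace
from dendrofit.features import load_feature_stats
from dendrofit.experiments import reference_model
from dendrofit.morphology import build_synthetic_l5b, compartmentalize


@pytest.fixture(scope="session")
def stats():
    return load_feature_stats()


@pytest.fixture(scope="session")
def ref_morphology():
    return build_synthetic_l5b()


@pytest.fixture(scope="session")
def ref_cell(ref_morphology):
    return compartmentalize(ref_morphology)


@pytest.fixture(scope="session")
def ref_model():
    """The published parameter set on the synthetic reference morphology."""
    return reference_model()


def triangle_train(spike_times, duration, dt=0.025, rest=-80.0, peak=40.0,
                   rise=1.0, fall=2.0):
    """Voltage trace of triangular APs: linear flanks make every
    threshold crossing exact under linear interpolation."""
    t = np.arange(0.0, duration + dt / 2, dt)
    v = np.full_like(t, rest)
    for ts in spike_times:
        up = (t >= ts) & (t < ts + rise)
        v[up] = np.maximum(v[up], rest + (peak - rest) * (t[up] - ts) / rise)
        down = (t >= ts + rise) & (t < ts + rise + fall)
        v[down] = np.maximum(
            v[down], peak - (peak - rest) * (t[down] - ts - rise) / fall)
    return Trace("V", "soma", 0.0, t, v)


def gaussian_train(spike_times, duration, dt=0.025, rest=-80.0, amp=120.0,
                   sigma=0.5):
    """Smooth synthetic spike train (Gaussian bumps) for resampling tests."""
    t = np.arange(0.0, duration + dt / 2, dt)
    v = np.full_like(t, rest)
    for ts in spike_times:
        v = v + amp * np.exp(-((t - ts) ** 2) / (2 * sigma**2))
    return Trace("V", "soma", 0.0, t, v)
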