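import numpy as np
import pytest

import pulsepol as pp
from pulsepol.simulator import PulseShape


@pytest.fixture(scope="session")
def identity_matrix():
    return pp.InstrumentMatrix(np.eye(4))


@pytest.fixture(scope="session")
def analyzer_matrix():
    return pp.default_instrument_matrix()


def make_labeled_traces(panel, n_particles, seed, noise_level=0.02, A=None):
    """Simulate pulses round-robin over a panel and calibrate them."""
    A = A or pp.default_instrument_matrix()
    rng = np.random.default_rng(seed)
    traces, labels = [], []
    for i in range(n_particles):
        pulse, label = pp.simulate_pulse(panel[i % len(panel)], A, noise_level, rng)
        traces.append(pp.to_stokes_trace(pulse, A))
        labels.append(label)
    return traces, labels


def mean_separable_panel(delta_q=0.6):
    """Two archetypes whose pulse averages alone separate them (q offset)."""
    shape = PulseShape(mean_width=35, width_dispersion=0.1, amplitude_log_sigma=0.2)
    common = dict(
        stokes_dispersion=(0.1, 0.05, 0.05, 0.03),
        stokes_jitter=(0.03, 0.03, 0.03, 0.02),
        shape=shape,
        fluorescence_dispersion=0.15,
    )
    return [
        pp.SpeciesArchetype(
            label="low_q", mean_stokes=(1.0, 0.1, 0.1, 0.05),
            fluorescence_level=0.5, **common,
        ),
        pp.SpeciesArchetype(
            label="high_q", mean_stokes=(1.0, 0.1 + delta_q, 0.1, 0.05),
            fluorescence_level=0.5, **common,
        ),
    ]


@pytest.fixture(scope="session")
def separable_dataset(analyzer_matrix):
    """Well-separated two-class feature table used across classifier tests."""
    traces, labels = make_labeled_traces(
        mean_separable_panel(), n_particles=1200, seed=11, A=analyzer_matrix
    )
    return pp.feature_frame(traces, mode="pfec", labels=labels)
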