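"""Shared fixtures for the test suite.

Expensive synthetic objects (epoch sets, RESS components) are module- or
session-scoped so that several tests can share one simulation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import assr_entrain as ae
from assr_entrain.mcgf import McgfParams

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def timeline():
    """Standard stimulation schedule: 40 trials x 6 s, 5 s ITI."""
    return ae.make_session_timeline(40, 6, 5)


@pytest.fixture(scope="session")
def fig_params():
    """The worked-example MCGF parameter set."""
    return McgfParams(A=1.0, d=1.0, mu=0.5, sigma=0.1, alpha=0.1)


@pytest.fixture(scope="session")
def clean_component(timeline):
    """Noise-free single-channel epochs with the stable-group envelope and a
    fixed per-trial phase spread."""
    cfg = ae.SynthConfig(
        carrier_env_params=McgfParams(A=1.0, d=1.0, mu=0.3, sigma=0.15, alpha=0.1),
        channel_labels=("Cz",), phase_jitter_sd=0.0, noise_scale=0.0, seed=7)
    return ae.simulate_assr_epochs(cfg, timeline)


@pytest.fixture(scope="session")
def noisy_epochs(timeline):
    """A realistic 14-channel epoch set (mixed-region-sized) with a planted
    40 Hz source, spatial gains and 1/f noise."""
    labels = ae.REGIONS["mixed"]
    rng = np.random.default_rng(11)
    gains = 0.2 + rng.random(len(labels))
    cfg = ae.SynthConfig(
        carrier_env_params=McgfParams(A=1.0, d=1.0, mu=0.3, sigma=0.15, alpha=0.1),
        channel_labels=labels, phase_jitter_sd=0.4,
        spatial_profile=tuple(gains), noise_scale=0.5, seed=11)
    return ae.simulate_assr_epochs(cfg, timeline), gains
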