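"""Shared fixtures: small synthetic sessions generated once per test run."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import erdsbci as eb

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

N_CH = 9  # compact sensorimotor patch around Cz


def make_alpha_config(seed: int, factor: float = 0.5, n_channels: int = N_CH) -> eb.SimulationConfig:
    """Session with a 10-Hz rhythm at Cz whose amplitude drops to
    ``factor`` during the imagery period (implants (factor²−1)·100 % ERD)."""
    return eb.SimulationConfig(
        n_channels=n_channels,
        oscillations=(
            eb.OscillationSpec(channel="Cz", center_freq=10.0, activity_factor=factor),
        ),
        seed=seed,
    )


def make_null_config(seed: int, n_channels: int = N_CH) -> eb.SimulationConfig:
    """Session with an unmodulated 10-Hz rhythm: no ERD/ERS anywhere."""
    return eb.SimulationConfig(
        n_channels=n_channels,
        oscillations=(
            eb.OscillationSpec(channel="Cz", center_freq=10.0, activity_factor=1.0),
        ),
        seed=seed,
    )


@pytest.fixture(scope="session")
def alpha_session():
    """(recording, events, truth, epochs) with −75% ERD implanted at Cz."""
    cfg = make_alpha_config(seed=0)
    recording, events, truth = eb.generate_session(cfg)
    epochs = eb.epoch(recording, events)
    return recording, events, truth, epochs


@pytest.fixture(scope="session")
def null_session():
    cfg = make_null_config(seed=1)
    recording, events, truth = eb.generate_session(cfg)
    epochs = eb.epoch(recording, events)
    return recording, events, truth, epochs


@pytest.fixture(scope="session")
def montage9():
    return eb.LaplacianMontage.hjorth(eb.compact_labels(N_CH))


@pytest.fixture(scope="session")
def alpha_features(alpha_session, montage9):
    _, _, _, epochs = alpha_session
    from erdsbci.classify import laplacian_features

    return laplacian_features(epochs, montage9)


@pytest.fixture(scope="session")
def null_features(null_session, montage9):
    _, _, _, epochs = null_session
    from erdsbci.classify import laplacian_features

    return laplacian_features(epochs, montage9)


@pytest.fixture(scope="session")
def fitted_armodel(montage9):
    cfg = make_null_config(seed=1)
    resting = eb.generate_resting(cfg, duration=90.0)
    return eb.fit_inverse_filter(resting, montage9)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
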