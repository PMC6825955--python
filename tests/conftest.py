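"""Shared fixtures: simulated sessions reused across test modules."""

import pytest

from monaural_adapt.listener import (
    ListenerModel,
    TrainingSchedule,
    simulate_session,
)


@pytest.fixture(scope="session")
def pre_model():
    return ListenerModel.plugged_pre()


@pytest.fixture(scope="session")
def post_model():
    return ListenerModel.plugged_post()


@pytest.fixture(scope="session")
def binaural_model():
    return ListenerModel.binaural()


@pytest.fixture(scope="session")
def pre_session(pre_model):
    """Plugged pre-adaptation test session, n = 1998."""
    return simulate_session(pre_model, "pre_test", 11, n_trials=1998)


@pytest.fixture(scope="session")
def post_session(post_model):
    """Plugged post-adaptation test session, n = 1998."""
    return simulate_session(post_model, "post_test", 12, n_trials=1998)


@pytest.fixture(scope="session")
def training_session(pre_model):
    """500-trial feedback training session with the default schedule."""
    return simulate_session(
        pre_model, "training", 7, schedule=TrainingSchedule()
    )


@pytest.fixture(scope="session")
def plugged_control_session(pre_model):
    """Plugged control session across the wide azimuth range, n = 3000."""
    return simulate_session(pre_model, "control_plugged", 13, n_trials=3000)


@pytest.fixture(scope="session")
def binaural_session(binaural_model):
    return simulate_session(binaural_model, "control_binaural", 14, n_trials=600)
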