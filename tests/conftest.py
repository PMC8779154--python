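"""Shared fixtures: small synthetic recordings and reduced-scale configs."""

from dataclasses import replace

import numpy as np
import pytest

import emgsleeve as es


@pytest.fixture(scope="session")
def short_protocol() -> es.SessionProtocol:
    """A compressed session protocol for fast tests (same structure)."""
    return replace(
        es.SessionProtocol(), calibration_s=4.0, hold_s=2.0, rest_s=3.0,
        n_datasets=2, train_fraction=1,
    )


@pytest.fixture(scope="session")
def default_session() -> es.EmgRecording:
    """One full default-protocol session (115 s, 7 channels, 1 kHz)."""
    return es.generate_session(es.SessionProtocol(), es.SynthConfig(), 1000.0,
                               seed=7)


@pytest.fixture(scope="session")
def short_session(short_protocol) -> es.EmgRecording:
    return es.generate_session(short_protocol, es.SynthConfig(), 1000.0, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def labeled_recording() -> es.EmgRecording:
    """A tiny 2-channel labeled recording for IO round-trip tests."""
    rng = np.random.default_rng(3)
    n = 50
    labels = [es.GestureClass.Rest] * 25 + [es.GestureClass.AllFingers] * 25
    return es.EmgRecording(rng.normal(size=(n, 2)), 1000.0,
                           channel_names=["ch1", "ch2"], labels=labels)
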