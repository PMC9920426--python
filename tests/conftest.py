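import logging

import numpy as np
import pytest

import falldet as fd
from falldet.data_model import ACTIVITY_CODES, Protocol


@pytest.fixture(autouse=True)
def _quiet_short_recording_warnings():
    logging.getLogger("falldet.windowing").setLevel(logging.ERROR)
    yield
    logging.getLogger("falldet.windowing").setLevel(logging.NOTSET)


@pytest.fixture(scope="session")
def small_protocol() -> Protocol:
    """Two young participants performing every activity."""
    participants = tuple((f"U{i:02d}", "YP", ACTIVITY_CODES) for i in (1, 2))
    return Protocol(participants=participants, repetitions={"F08": 4})


@pytest.fixture(scope="session")
def small_dataset(small_protocol):
    return fd.generate_dataset(small_protocol, seed=11)


@pytest.fixture(scope="session")
def fall_recording():
    return fd.generate_fall("F03", seed=5)


@pytest.fixture(scope="session")
def walk_recording():
    return fd.generate_adl("D01", seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
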