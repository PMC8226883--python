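import numpy as np
import pytest

from p300kit.preprocessing import preprocess_pipeline
from p300kit.synthetic import SessionSpec, generate_session


@pytest.fixture(scope="session")
def four_choice_session():
    spec = SessionSpec(paradigm="four_choice", n_repetitions=2, n_selections=30,
                       snr=1.5, seed=11)
    return generate_session(spec)


@pytest.fixture(scope="session")
def four_choice_symbols(four_choice_session):
    recording, schedule, _ = four_choice_session
    return preprocess_pipeline(recording, schedule)


@pytest.fixture(scope="session")
def speller_session():
    spec = SessionSpec(paradigm="speller6x6", n_repetitions=3, n_selections=4,
                       snr=1.0, seed=7)
    return generate_session(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
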