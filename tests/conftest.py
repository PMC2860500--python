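"""Shared fixtures: one seeded synthetic session reused across test modules."""

import numpy as np
import pytest
from hypothesis import settings

import popdecode as pp

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def patterns():
    return pp.enumerate_patterns()


@pytest.fixture(scope="session")
def pmat():
    return pp.pattern_matrix()


@pytest.fixture(scope="session")
def kernel():
    return pp.biphasic_kernel()


@pytest.fixture(scope="session")
def session10():
    """Ten interleaved repetitions of both paradigms (the study layout)."""
    return pp.build_session(10, seed=11)


@pytest.fixture(scope="session")
def units():
    return pp.make_population(pp.PopulationConfig(seed=7))


@pytest.fixture(scope="session")
def relay_tensor(session10, units, kernel):
    return pp.simulate_responses(session10.relay, units, kernel, seed=21)


@pytest.fixture(scope="session")
def dict_tensor(session10, units, kernel):
    return pp.simulate_responses(session10.dictionary, units, kernel, seed=22)


@pytest.fixture(scope="session")
def noiseless_relay_tensor(session10, units, kernel):
    return pp.simulate_responses(session10.relay, units, kernel, noiseless=True)


@pytest.fixture(scope="session")
def noiseless_dict_tensor(session10, units, kernel):
    return pp.simulate_responses(session10.dictionary, units, kernel, noiseless=True)


@pytest.fixture(scope="session")
def decoder(dict_tensor, session10):
    return pp.DictionaryDecoder().fit(dict_tensor, session10.dictionary)


@pytest.fixture(scope="session")
def relay_trace(decoder, relay_tensor, session10):
    return decoder.trace(relay_tensor, session10.relay)


@pytest.fixture(scope="session")
def orientation_stimuli():
    return pp.orientation_test_stimuli()


@pytest.fixture(scope="session")
def info_trace(relay_tensor, session10, dict_tensor):
    sites = np.flatnonzero(pp.significance_mask(dict_tensor, session10.dictionary))
    return pp.information_trace(
        relay_tensor, session10.relay, sites=sites, rng=np.random.default_rng(31)
    )
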