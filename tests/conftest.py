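"""Shared fixtures: small phantoms and synthetic cohorts, built once per session."""
import numpy as np
import pytest

from perfcortex import (
    AcqParams,
    CohortSimConfig,
    pvec_correct,
    quantify_volume,
    simulate_cohort,
    simulate_phantom,
)


@pytest.fixture(scope="session")
def acq_noiseless():
    return AcqParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def acq_default():
    return AcqParams()


@pytest.fixture(scope="session")
def phantom_noiseless(acq_noiseless):
    return simulate_phantom(acq=acq_noiseless, seed=0)


@pytest.fixture(scope="session")
def pvec_noiseless(phantom_noiseless):
    ph = phantom_noiseless
    return pvec_correct(ph.control4d, ph.label4d, ph.probmaps)


@pytest.fixture(scope="session")
def cbf_noiseless(pvec_noiseless, acq_noiseless):
    return quantify_volume(pvec_noiseless, acq_noiseless)


@pytest.fixture(scope="session")
def phantom_noisy(acq_default):
    return simulate_phantom(acq=acq_default, seed=0)


@pytest.fixture(scope="session")
def pvec_noisy(phantom_noisy):
    ph = phantom_noisy
    return pvec_correct(ph.control4d, ph.label4d, ph.probmaps)


@pytest.fixture(scope="session")
def cohort28():
    return simulate_cohort(CohortSimConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
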