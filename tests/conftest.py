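import numpy as np
import pytest
from hypothesis import settings

import brnuq as bq

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def decay_model():
    return bq.make_model("decay")


@pytest.fixture(scope="session")
def conserved_model():
    return bq.make_model("conserved_pair")


@pytest.fixture(scope="session")
def mm_model():
    return bq.make_model("mm_cascade")


@pytest.fixture(scope="session")
def mm_spec():
    return bq.default_spec("mm_cascade")


@pytest.fixture(scope="session")
def mm_with_data(mm_model, mm_spec):
    return bq.make_data(mm_model, mm_spec)


@pytest.fixture(scope="session")
def mm_prior_sample():
    """100 draws from the full mm_cascade fixture prior (log10 scale)."""
    prior = bq.fixture_prior("mm_cascade")
    rng = np.random.default_rng(3)
    return bq.ParameterSample(prior.sample_log10(rng, 100), "log10")


@pytest.fixture(scope="session")
def mm_ensembles(mm_with_data, mm_prior_sample):
    t_grid = np.linspace(0.0, 10.0, 25)
    return bq.propagate(mm_with_data, mm_prior_sample, mm_with_data.experiments[0], t_grid)
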